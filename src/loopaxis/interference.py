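"""ChIP-qPCR percent-input quantification and the DSB-interference statistic.

Double-strand-break (DSB) interference at a pair of hotspots (sites I and II)
is quantified from Southern-blot band fractions on the same chromatid:

    I = 1 - DC_observed / DC_expected

where DC_observed is the double-cut frequency and DC_expected = f1 * f2 is
the product of the single-site cut frequencies expected under independence.
Positive I means coincident cuts are suppressed (interference), I = 0 means
independence, and negative I means concerted cutting.

Two measurement corrections apply to the short-range assay. First, the
central probe used to quantify double-cuts hybridises to ``m`` parental loci
(m = 3 by default), so the raw double-cut band fraction under-reports by a
factor m and is multiplied back. Second, molecules cut at both sites leave
the band that reports site II, so the site-II single-cut frequency is
under-measured; DC_observed is added back to it before forming the expected
product. The mid-range (pulsed-field) assay uses the plain product of the two
measured single-cut frequencies with no loss correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrMeasurement", "BlotQuant", "InterferenceResult",
           "percent_ip", "observed_dc", "expected_dc", "interference_value",
           "interference_from_blot"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One locus quantified in IP and input material against a standard curve.

    ``dilution_factor`` is how much more dilute the input is when loaded on
    the qPCR plate (20-fold here); ``volume_factor`` is the ratio of material
    volumes between the input aliquot and the IP (10-fold here).
    """

    q_ip: float
    q_input: float
    dilution_factor: float = 20.0
    volume_factor: float = 10.0

    def __post_init__(self):
        if self.q_input <= 0:
            raise ValueError("q_input must be positive")
        if self.dilution_factor <= 0 or self.volume_factor <= 0:
            raise ValueError("correction factors must be positive")


def percent_ip(m: QpcrMeasurement) -> float:
    """Percent of input immunoprecipitated at the locus:
    %IP = 100 * q_ip / (q_input * D * V)."""
    return 100.0 * m.q_ip / (m.q_input * m.dilution_factor * m.volume_factor)


@dataclass(frozen=True)
class BlotQuant:
    """Band fractions from one lane of a Southern blot.

    ``f1``: single-cut frequency at site I; ``f2_raw``: site-II frequency as
    measured (depleted by double cuts in the short-range assay);
    ``dc_central_raw``: double-cut band fraction from the central probe;
    ``probe_loci``: number of genomic loci that probe hybridises to.
    Frequencies are fractions of total lane signal in [0, 1]; percent inputs
    may be passed with ``units='percent'`` to the helpers below.
    """

    f1: float
    f2_raw: float
    dc_central_raw: float
    probe_loci: int = 3

    def __post_init__(self):
        for name in ("f1", "f2_raw", "dc_central_raw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.probe_loci < 1:
            raise ValueError("probe_loci must be >= 1")


@dataclass(frozen=True)
class InterferenceResult:
    """Observed and expected double-cut frequencies and I = 1 - obs/exp.

    ``interference`` is NaN when both frequencies are 0 (uninformative lane).
    """

    dc_obs: float
    dc_exp: float
    interference: float


def observed_dc(b: BlotQuant) -> float:
    """Correct the central-probe double-cut fraction for probe multiplicity:
    DC_obs = m * dc_central_raw."""
    dc = b.probe_loci * b.dc_central_raw
    if dc > 1.0:
        raise ValueError(
            f"corrected double-cut frequency {dc} exceeds 1; "
            "band quantification inconsistent with probe multiplicity")
    return dc


def expected_dc(b: BlotQuant, dc_obs: float, dc_loss_correction: bool = True) -> float:
    """Expected double-cut frequency under independent cutting.

    With the loss correction (short-range assay) the double cuts missing
    from the site-II band are restored first: DC_exp = f1 * (f2_raw + DC_obs).
    Without it (mid-range assay): DC_exp = f1 * f2_raw.
    """
    if not 0.0 <= dc_obs <= 1.0:
        raise ValueError("dc_obs outside [0, 1]")
    f2 = b.f2_raw + dc_obs if dc_loss_correction else b.f2_raw
    if f2 > 1.0:
        raise ValueError(f"corrected site-II frequency {f2} exceeds 1")
    return b.f1 * f2


def interference_value(dc_obs: float, dc_exp: float) -> InterferenceResult:
    """I = 1 - DC_obs / DC_exp; positive = interference, 0 = independence,
    negative = concerted double-cutting."""
    if dc_obs < 0 or dc_exp < 0:
        raise ValueError("frequencies must be non-negative")
    if dc_exp == 0:
        if dc_obs > 0:
            raise ValueError("expected double-cut frequency is 0 but double "
                             "cuts were observed; interference undefined")
        return InterferenceResult(dc_obs=0.0, dc_exp=0.0,
                                  interference=math.nan)
    return InterferenceResult(dc_obs=dc_obs, dc_exp=dc_exp,
                              interference=1.0 - dc_obs / dc_exp)


def interference_from_blot(b: BlotQuant, mode: str = "short") -> InterferenceResult:
    """Full pipeline from band fractions to I.

    ``mode='short'`` applies both the probe-multiplicity and the
    double-cut-loss corrections; ``mode='mid'`` uses the plain product of the
    measured single-cut frequencies.
    """
    if mode not in ("short", "mid"):
        raise ValueError(f"unknown mode {mode!r}")
    dc_obs = observed_dc(b)
    dc_exp = expected_dc(b, dc_obs, dc_loss_correction=(mode == "short"))
    return interference_value(dc_obs, dc_exp)
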