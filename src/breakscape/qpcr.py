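"""qPCR-derived assay quantifications.

All assays assume perfect amplification efficiency (E = 2, one cycle per
doubling) unless stated otherwise, so quantities are powers of two in Ct
differences.  Every formula is scale-free in absolute Ct: adding a constant
to all cycle thresholds leaves the result unchanged.

Assays
------
* ``ssdna_percent`` - single-stranded DNA percent from a differential
  restriction-digest pair (resection readout).
* ``percent_broken`` - repair kinetics: fraction of break sites still open
  relative to the peak-damage reference time point.
* ``ddct_frequency`` - translocation (illegitimate rejoining) frequency by
  the ddCt method against the mean of two control amplicons.
* ``drip_percent_input`` - DRIP-qPCR hybrid signal as percent of input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CtMeasurement",
    "AssayResult",
    "ssdna_percent",
    "resection_normalized",
    "percent_broken",
    "ddct_frequency",
    "drip_percent_input",
    "summarize_replicates",
]


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR cycle-threshold record."""

    sample: str
    target: str
    condition: str
    replicate: int
    ct: float

    def __post_init__(self):
        if not math.isfinite(self.ct):
            raise ValueError(f"Ct must be finite, got {self.ct}")


@dataclass
class AssayResult:
    """Replicate-aggregated assay value (mean and s.e.m.)."""

    assay: str
    target: str
    condition: str
    replicate_values: list[float]
    mean: float
    sem: float
    sem_defined: bool = True

    @property
    def value(self) -> float:
        return self.mean


def _require_finite(*cts: float) -> None:
    for ct in cts:
        if not math.isfinite(ct):
            raise ValueError(f"non-finite Ct {ct}")


def ssdna_percent(ct_digested: float, ct_undigested: float,
                  clamp: bool = True) -> float:
    """Percent single-stranded DNA from a digested/undigested Ct pair.

    ssDNA% = 1 / (2^(dCt - 1) + 0.5) x 100 with dCt = Ct_dig - Ct_undig.
    Strictly decreasing in dCt; dCt = 0 (digest-resistant, fully
    single-stranded at the probe) gives 100.  The raw expression ranges up
    to 200 as dCt -> -inf; by default values above 100 are clamped to 100
    (pass ``clamp=False`` for the raw value).
    """
    _require_finite(ct_digested, ct_undigested)
    dct = ct_digested - ct_undigested
    raw = 1.0 / (2.0 ** (dct - 1.0) + 0.5) * 100.0
    return float(min(raw, 100.0)) if clamp else float(raw)


def resection_normalized(sample_ssdna: float, control_undamaged_ssdna: float) -> float:
    """Fold ssDNA relative to the undamaged control (the pre-induction %)."""
    if control_undamaged_ssdna <= 0:
        raise ValueError("control ssDNA% must be positive")
    return float(sample_ssdna) / float(control_undamaged_ssdna)


def percent_broken(ct_pulldown_t: float, ct_input_t: float,
                   ct_pulldown_ref: float, ct_input_ref: float) -> float:
    """Percent of sites still broken at time t vs the peak-damage reference.

    The broken-end signal at a time point is the input-normalized pulldown
    quantity s(t) = 2^(Ct_input(t) - Ct_pulldown(t)); the readout is
    100 x s(t) / s(ref), which is 100 at the reference by construction.
    Values above 100 (pulldown stronger than at reference) are reported
    as-is and should be flagged downstream.
    """
    _require_finite(ct_pulldown_t, ct_input_t, ct_pulldown_ref, ct_input_ref)
    s_t = 2.0 ** (ct_input_t - ct_pulldown_t)
    s_ref = 2.0 ** (ct_input_ref - ct_pulldown_ref)
    return float(100.0 * s_t / s_ref)


def ddct_frequency(ct_target: dict[str, float],
                   ct_controls: dict[str, dict[str, float]],
                   reference_condition: str) -> dict[str, float]:
    """Relative junction frequency per condition by the ddCt method.

    ``ct_target`` maps condition -> target (junction) Ct.  ``ct_controls``
    maps control amplicon name -> {condition: Ct} for exactly two control
    regions.  Per condition the control Ct is the arithmetic mean of the
    two control Cts (the geometric mean of their quantities);
    dCt = Ct_target - mean(control Cts) and the result is
    2^-(dCt_condition - dCt_reference), hence 1 at the reference.
    """
    if len(ct_controls) != 2:
        raise ValueError(
            f"exactly two control amplicons required, got {sorted(ct_controls)}"
        )
    if reference_condition not in ct_target:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    for name, by_cond in ct_controls.items():
        for cond in ct_target:
            if cond not in by_cond:
                raise ValueError(
                    f"control amplicon {name!r} missing condition {cond!r}"
                )
    def dct(cond: str) -> float:
        ctrl = float(np.mean([ct_controls[name][cond] for name in ct_controls]))
        _require_finite(ct_target[cond], ctrl)
        return ct_target[cond] - ctrl

    ref = dct(reference_condition)
    return {cond: float(2.0 ** -(dct(cond) - ref)) for cond in ct_target}


def drip_percent_input(ct_ip: float, ct_input: float,
                       input_fraction: float) -> float:
    """DRIP-qPCR signal as percent of input.

    ``input_fraction`` is the fraction of material reserved as input
    (e.g. 10 of 460 uL); result = 100 x fraction x 2^(Ct_input - Ct_ip).
    """
    _require_finite(ct_ip, ct_input)
    if not (0.0 < input_fraction < 1.0):
        raise ValueError(
            f"input_fraction must be in (0, 1), got {input_fraction}"
        )
    return float(100.0 * input_fraction * 2.0 ** (ct_input - ct_ip))


def drip_enrichment(ct_ip: float, ct_input: float, ct_ip_neg: float,
                    ct_input_neg: float) -> float:
    """DRIP signal as fold enrichment over a negative control region."""
    _require_finite(ct_ip, ct_input, ct_ip_neg, ct_input_neg)
    return float(2.0 ** ((ct_input - ct_ip) - (ct_input_neg - ct_ip_neg)))


def summarize_replicates(values, assay: str = "", target: str = "",
                         condition: str = "") -> AssayResult:
    """Mean and s.e.m. (sample sd / sqrt(n)) over biological replicates.

    Aggregation happens after per-replicate assay computation, never on
    pooled Cts.  With a single replicate the s.e.m. is reported as 0 and
    flagged undefined.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no replicate values")
    n = len(vals)
    mean = float(np.mean(vals))
    if n == 1:
        return AssayResult(assay=assay, target=target, condition=condition,
                           replicate_values=vals, mean=mean, sem=0.0,
                           sem_defined=False)
    sem = float(np.std(vals, ddof=1) / math.sqrt(n))
    return AssayResult(assay=assay, target=target, condition=condition,
                       replicate_values=vals, mean=mean, sem=sem)
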