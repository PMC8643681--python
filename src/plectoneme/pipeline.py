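"""The two-gel band-counting protocol as one reproducible pipeline.

One supercoiling measurement uses two first-dimension runs of the same
sample: one without intercalator (reading the writhe the plasmid carries at
gel temperature) and one with chloroquine (relaxing extreme topoisomers into
the countable range).  The difference between the two major-topoisomer
writhes gives the chloroquine shift; the temperature shift follows from the
growth-to-gel temperature difference; subtracting both from the
chloroquine-gel reading yields the native writhe and hence sigma = Wr/Tw.

When the plasmid is so supercoiled that the no-chloroquine gel shows only a
saturated front band, the chloroquine shift cannot be measured on that
sample: it must be transferred from a control sample measured under the same
conditions and passed in explicitly (``delta_wr_chl``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .bands import BandLadder, major_topoisomer
from .topology import (
    CorrectionParameters,
    PlasmidSpec,
    SupercoilingResult,
    chloroquine_shift_from_gels,
    temperature_writhe_shift,
)

__all__ = [
    "TwoGelExperiment",
    "UnresolvableFrontBandError",
    "run_two_gel_protocol",
    "ReplicateSummary",
    "aggregate_replicates",
    "SigmaFoldChange",
    "fold_change_sigma",
]


class UnresolvableFrontBandError(ValueError):
    """The counting gel shows only a saturated front band.

    Extreme supercoiling: individual topoisomers did not separate, so no
    major-band writhe can be counted.  Re-run with (more) chloroquine in the
    first dimension, or supply a chloroquine shift calibrated on a control
    sample.
    """


@dataclass(frozen=True)
class TwoGelExperiment:
    """Both first-dimension ladders of one sample plus the run conditions."""

    plasmid: PlasmidSpec
    growth_temp_C: float
    gel_temp_C: float
    ladder_with_chl: BandLadder
    chloroquine_ug_ml: float
    ladder_no_chl: BandLadder | None = None
    params: CorrectionParameters = CorrectionParameters()

    def __post_init__(self) -> None:
        if self.chloroquine_ug_ml <= 0:
            raise ValueError("the counting gel must contain chloroquine (> 0 ug/ml)")


def _major_writhe(ladder: BandLadder, which: str) -> int:
    if ladder.saturated_front:
        raise UnresolvableFrontBandError(
            f"{which} gel: extreme supercoiling, only a front band -- "
            "a chloroquine counting gel (or an external chloroquine shift) is required"
        )
    idx = major_topoisomer(ladder)
    wr = ladder.bands[idx].assigned_writhe
    if wr is None:
        raise ValueError(f"{which} gel: major band has no assigned writhe")
    return wr


def run_two_gel_protocol(
    exp: TwoGelExperiment, delta_wr_chl: float | None = None
) -> SupercoilingResult:
    """Run the full band-counting calculation for one sample.

    If ``delta_wr_chl`` is None it is measured from the sample's own gel
    pair; otherwise the supplied value (calibrated on a control sample under
    identical conditions) is used and the no-chloroquine ladder is not
    consulted.  Every intermediate is retained in the result for audit.
    """
    wr_apparent = _major_writhe(exp.ladder_with_chl, "chloroquine")
    if delta_wr_chl is None:
        if exp.ladder_no_chl is None:
            raise ValueError(
                "need either the no-chloroquine ladder or an explicit delta_wr_chl"
            )
        wr_without = _major_writhe(exp.ladder_no_chl, "no-chloroquine")
        delta_wr_chl = chloroquine_shift_from_gels(wr_apparent, wr_without)
    delta_wr_temp = temperature_writhe_shift(
        exp.plasmid, exp.growth_temp_C, exp.gel_temp_C, exp.params
    )
    return SupercoilingResult(
        plasmid=exp.plasmid,
        wr_apparent=wr_apparent,
        delta_wr_chloroquine=delta_wr_chl,
        delta_wr_temperature=delta_wr_temp,
    )


@dataclass(frozen=True)
class ReplicateSummary:
    mean_sigma: float
    sd_sigma: float | None  # None when n == 1 (sample SD undefined)
    n: int


def aggregate_replicates(results: list[SupercoilingResult]) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) of sigma across replicates."""
    if not results:
        raise ValueError("no replicates")
    plasmids = {r.plasmid for r in results}
    if len(plasmids) > 1:
        names = sorted(p.name for p in plasmids)
        raise ValueError(f"replicates mix plasmids: {names}")
    sigmas = [r.sigma for r in results]
    n = len(sigmas)
    mean = sum(sigmas) / n
    if n == 1:
        return ReplicateSummary(mean_sigma=mean, sd_sigma=None, n=1)
    var = sum((s - mean) ** 2 for s in sigmas) / (n - 1)
    return ReplicateSummary(mean_sigma=mean, sd_sigma=math.sqrt(var), n=n)


@dataclass(frozen=True)
class SigmaFoldChange:
    """Both readings of a 'fold change in supercoiling density'.

    ``ratio`` = |sigma_test| / |sigma_control| and ``delta_sigma`` =
    sigma_test - sigma_control; which one a given report means by
    "x-fold" is ambiguous, so both are surfaced.
    """

    ratio: float
    delta_sigma: float


def fold_change_sigma(
    test: SupercoilingResult | float, control: SupercoilingResult | float
) -> SigmaFoldChange:
    """Magnitude ratio and signed difference of two supercoiling densities."""
    s_test = test.sigma if isinstance(test, SupercoilingResult) else float(test)
    s_ctrl = control.sigma if isinstance(control, SupercoilingResult) else float(control)
    if s_ctrl == 0.0:
        warnings.warn("control sigma is zero; ratio reported as infinite", stacklevel=2)
        ratio = math.inf
    else:
        ratio = abs(s_test) / abs(s_ctrl)
    return SigmaFoldChange(ratio=ratio, delta_sigma=s_test - s_ctrl)
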