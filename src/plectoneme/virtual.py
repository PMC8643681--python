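"""End-to-end virtual experiments: simulate gels, analyze them, recover sigma.

This module closes the loop between the gel simulator and the band-counting
pipeline for validation by parameter recovery.  A virtual measurement of one
sample proceeds exactly as at the bench:

1. render the sample's 2D gel (chloroquine in the first dimension for the
   counting gel, none for the reference gel);
2. split the spot pattern into the two arcs -- species with equal
   first-dimension mobility but opposite writhe sign separate along the
   second dimension, on either side of the ordinate of a hypothetical
   dimension-1-relaxed species.  This is the analyst's "which arc is the
   population on?" step, done geometrically, without ground truth;
3. profile each arc along dimension 1, pick peaks, and count writhe from
   the origin (relaxed/nicked position) on the integer grid implied by the
   inter-band spacing;
4. the most intense band across arcs is the major topoisomer; its signed
   effective writhe is the gel's apparent writhe.

The chloroquine shift is calibrated once from a control sample whose
topoisomers are countable on both gels, then transferred to samples whose
no-chloroquine gel shows only a front band -- the reason the counting gel
contains intercalator in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import BandLadder, detect_bands, major_topoisomer
from .gelsim import (
    GelConditions,
    TopoisomerDistribution,
    dim2_saturation,
    migrate,
    profile_from_bands,
    render_gel,
    sample_topoisomers,
)
from .pipeline import (
    TwoGelExperiment,
    UnresolvableFrontBandError,
    run_two_gel_protocol,
)
from .topology import CorrectionParameters, PlasmidSpec, SupercoilingResult

__all__ = [
    "GelReading",
    "read_apparent_writhe",
    "calibrate_control_shift",
    "VirtualMeasurement",
    "measure_virtual_sample",
]


@dataclass(frozen=True)
class GelReading:
    """Apparent (signed effective) writhe of the major band on one gel."""

    wr_apparent: int
    sign_direction: int
    ladder: BandLadder
    saturated: bool


def _arc_sign_boundary(
    plasmid: PlasmidSpec, gel: GelConditions, params: CorrectionParameters
) -> float:
    """Dimension-2 ordinate of a species that is relaxed in dimension 1.

    Species on the faster side of this ordinate in dimension 2 carried
    positive effective writhe in dimension 1, species on the slower side
    negative: the two arcs.  Pure gel geometry; no ground truth needed.
    """
    d1 = params.chloroquine_unwinding_per_ug_ml_per_bp * gel.chloroquine_dim1_ug_ml
    d2 = params.chloroquine_unwinding_per_ug_ml_per_bp * gel.chloroquine_dim2_ug_ml
    wr_eff2_of_dim1_relaxed = (d2 - d1) * plasmid.length_bp
    return migrate(
        wr_eff2_of_dim1_relaxed, gel, saturation=dim2_saturation(plasmid, gel, params)
    )


def _arc_ladder(
    spots: pd.DataFrame,
    gel: GelConditions,
    min_prominence: float,
) -> BandLadder:
    """1D profile + peak detection for the spots of one arc."""
    axis = np.arange(
        -6.0 * gel.band_width, gel.migration_max + 6.0 * gel.band_width + 0.2, 0.2
    )
    profile = profile_from_bands(
        spots["dimension1_position"].to_numpy(),
        spots["intensity"].to_numpy(),
        gel.band_width,
        axis=axis,
    )
    ladder = detect_bands(
        profile, min_prominence=min_prominence, min_separation=2.0 * gel.band_width
    )
    ref = int(np.argmin(np.abs(ladder.positions))) if len(ladder) else None
    return replace(ladder, reference_index=ref)


def read_apparent_writhe(
    spots: pd.DataFrame,
    plasmid: PlasmidSpec,
    gel: GelConditions,
    params: CorrectionParameters = CorrectionParameters(),
    min_prominence: float = 1e-3,
) -> GelReading:
    """Read the major topoisomer's signed effective writhe off a 2D spot table.

    Implements steps 2--4 of the module docstring.  ``min_prominence`` is
    relative to the total lane intensity.
    """
    spots = spots.copy()
    y0 = _arc_sign_boundary(plasmid, gel, params)
    # nicked species (origin in both dimensions) is a position marker only
    closed = spots[
        ~((spots["dimension1_position"] == 0.0) & (spots["dimension2_position"] == 0.0))
    ]
    if closed.empty:
        raise ValueError("no closed-circular species on the gel")
    tol = 1e-6 * gel.migration_max
    total = float(closed["intensity"].sum())
    prominence = min_prominence * total
    step = gel.migration_max / gel.mobility_saturation_wr  # gel units per supercoil

    # Species exactly on the boundary (relaxed in dimension 1) join the
    # positive arc: they are counted as k = 0, where the sign is moot.
    y = closed["dimension2_position"]
    arcs: dict[int, pd.DataFrame] = {
        +1: closed[y >= y0 - tol],
        -1: closed[y < y0 - tol],
    }

    # The front band (index >= S) is a pile-up of every topoisomer beyond
    # the resolution limit, not a single species: it is never a major-band
    # candidate, but if it outshines every resolved band the population
    # mode is at or beyond the front and the gel cannot be counted.
    S = gel.mobility_saturation_wr
    resolved: list[tuple[float, int, int, BandLadder]] = []
    front_max = 0.0
    for sign, sub in arcs.items():
        if sub.empty:
            continue
        ladder = _arc_ladder(sub, gel, prominence)
        if len(ladder) == 0:
            continue
        pos = ladder.positions
        if len(ladder) > 1:
            grid = float(np.diff(pos).min())
        else:
            grid = step  # single band: fall back to the gel's calibrated spacing
        for i, band in enumerate(ladder.bands):
            k = int(round(abs(pos[i]) / grid))
            if k >= S:
                front_max = max(front_max, band.intensity)
            else:
                resolved.append((band.intensity, sign, k, ladder))
    if not resolved and front_max == 0.0:
        raise ValueError("no bands detected on the gel")
    if not resolved or front_max > max(c[0] for c in resolved):
        ladder = resolved[0][3] if resolved else BandLadder(bands=())
        return GelReading(
            wr_apparent=0, sign_direction=+1, ladder=ladder, saturated=True
        )

    best = max(resolved, key=lambda c: c[0])
    _, sign, k, ladder = best
    return GelReading(
        wr_apparent=sign * k, sign_direction=sign, ladder=ladder, saturated=False
    )


def calibrate_control_shift(
    plasmid: PlasmidSpec,
    control_center_writhe: int,
    growth_temp_C: float,
    gel_counting: GelConditions,
    gel_reference: GelConditions,
    params: CorrectionParameters = CorrectionParameters(),
    spread: float = 1.5,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> float:
    """Chloroquine shift from a control sample countable on both gels.

    Simulates the control population once, reads the major-band writhe on
    the counting (with-chloroquine) and reference (no-chloroquine) gels and
    returns their difference.
    """
    dist = sample_topoisomers(
        plasmid, control_center_writhe, spread, n_molecules, seed, nicked_fraction=0.03
    )
    readings = []
    for gel in (gel_counting, gel_reference):
        spots = render_gel(dist, gel, growth_temp_C, params, mode="2D")
        readings.append(read_apparent_writhe(spots, plasmid, gel, params))
    return float(readings[0].wr_apparent - readings[1].wr_apparent)


@dataclass(frozen=True)
class VirtualMeasurement:
    result: SupercoilingResult
    reading: GelReading
    resolvable: bool


def measure_virtual_sample(
    plasmid: PlasmidSpec,
    native_center_writhe: int,
    growth_temp_C: float,
    gel_counting: GelConditions,
    delta_wr_chl: float,
    params: CorrectionParameters = CorrectionParameters(),
    spread: float = 1.5,
    n_molecules: int = 100_000,
    seed: int = 0,
    nicked_fraction: float = 0.03,
) -> VirtualMeasurement:
    """Simulate one sample, read its counting gel, run the sigma pipeline.

    Raises :class:`UnresolvableFrontBandError` when the major band sits at
    the mobility front (\\|effective writhe\\| at or beyond the saturation
    writhe): the counting method has nothing to count there.
    """
    dist = sample_topoisomers(
        plasmid,
        native_center_writhe,
        spread,
        n_molecules,
        seed,
        nicked_fraction=nicked_fraction,
    )
    spots = render_gel(dist, gel_counting, growth_temp_C, params, mode="2D")
    reading = read_apparent_writhe(spots, plasmid, gel_counting, params)
    if reading.saturated:
        raise UnresolvableFrontBandError(
            "major band at the mobility front: extreme supercoiling, "
            "not countable under these gel conditions"
        )
    ladder = replace(reading.ladder, saturated_front=False)
    exp = TwoGelExperiment(
        plasmid=plasmid,
        growth_temp_C=growth_temp_C,
        gel_temp_C=gel_counting.temperature_C,
        ladder_with_chl=_with_major_writhe(ladder, reading.wr_apparent),
        chloroquine_ug_ml=gel_counting.chloroquine_dim1_ug_ml,
        params=params,
    )
    result = run_two_gel_protocol(exp, delta_wr_chl=delta_wr_chl)
    return VirtualMeasurement(result=result, reading=reading, resolvable=True)


def _with_major_writhe(ladder: BandLadder, wr_apparent: int) -> BandLadder:
    """Stamp the signed apparent writhe onto the ladder's major band.

    The arc reading yields one signed writhe (for the major band); the
    pipeline only consumes the major band's writhe, so the remaining bands
    keep offsets relative to it along the migration axis.
    """
    idx = major_topoisomer(ladder)
    pos = ladder.positions
    if len(ladder) > 1:
        grid = float(np.diff(pos).min())
        offsets = np.round((pos - pos[idx]) / grid).astype(int)
    else:
        offsets = np.array([0])
    sign = 1 if wr_apparent >= 0 else -1
    bands = tuple(
        replace(b, assigned_writhe=int(wr_apparent + sign * o))
        for b, o in zip(ladder.bands, offsets)
    )
    return replace(ladder, bands=bands)
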