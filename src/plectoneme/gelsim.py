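"""Virtual chloroquine agarose gels for topoisomer populations of known topology.

A topoisomer population is a discrete distribution over integer native
writhe.  Rendering a virtual gel applies the same physics the topology
module corrects for, in the forward direction:

* temperature: the sample equilibrates at the gel temperature before the
  run, shifting every topoisomer's writhe by the temperature correction;
* chloroquine: intercalation unwinds the helix linearly in concentration,
  shifting writhe positive by ``u * c * N`` turns (``u`` calibrated from the
  single available measurement of 19 supercoils at 1.5 ug/ml on a 5455 bp
  plasmid);
* mobility: migration distance grows linearly with \\|effective writhe\\| up to
  a saturation writhe ``S`` beyond which all species co-migrate as one
  front band.  Nicked (open-circular) molecules stay at the origin.

Rendered output is either a 1D intensity profile (sum of Gaussian bands
plus optional noise) or a 2D spot table whose two coordinates use the
dimension-1 and dimension-2 chloroquine concentrations; species with equal
first-dimension mobility but opposite writhe sign separate in the second
dimension, producing the two arcs used to sign the supercoiling.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import (
    CorrectionParameters,
    PlasmidSpec,
    temperature_writhe_shift,
)

__all__ = [
    "TopoisomerDistribution",
    "GelConditions",
    "sample_topoisomers",
    "calibrate_chloroquine_coefficient",
    "effective_writhe",
    "migrate",
    "dim2_saturation",
    "render_gel",
    "profile_from_bands",
    "plot_gel_2d",
]


@dataclass(frozen=True)
class TopoisomerDistribution:
    """A population over integer native writhe, plus a nicked fraction.

    ``entries`` maps distinct integer writhes to non-negative abundances
    (arbitrary units, e.g. molecule counts).  ``nicked_fraction`` is the
    fraction of *all* molecules that are nicked open circles (zero mobility,
    no defined writhe).
    """

    plasmid: PlasmidSpec
    entries: tuple[tuple[int, float], ...]
    nicked_fraction: float = 0.0

    def __post_init__(self) -> None:
        writhes = [w for w, _ in self.entries]
        if len(set(writhes)) != len(writhes):
            raise ValueError("writhe values must be distinct integers")
        total = sum(a for _, a in self.entries)
        if total <= 0 or any(a < 0 for _, a in self.entries):
            raise ValueError("abundances must be non-negative with positive total")
        if not 0.0 <= self.nicked_fraction < 1.0:
            raise ValueError("nicked_fraction must be in [0, 1)")

    @property
    def total_closed(self) -> float:
        return float(sum(a for _, a in self.entries))

    @property
    def nicked_abundance(self) -> float:
        """Abundance of the nicked species on the same scale as ``entries``."""
        if self.nicked_fraction == 0.0:
            return 0.0
        return self.total_closed * self.nicked_fraction / (1.0 - self.nicked_fraction)

    def mean_writhe(self) -> float:
        w = np.array([w for w, _ in self.entries], dtype=float)
        a = np.array([a for _, a in self.entries], dtype=float)
        return float((w * a).sum() / a.sum())


@dataclass(frozen=True)
class GelConditions:
    """Run conditions of one virtual 2D gel.

    ``mobility_saturation_wr`` (S) is the \\|effective writhe\\| beyond which
    bands co-migrate as a single front band in the first dimension; 20 is a
    reasonable default for a ~5 kb plasmid on 0.8% agarose, where ladders of
    roughly +-20 topoisomers are countable.  ``migration_max`` sets the
    front-band position in arbitrary gel units; ``band_width`` is the
    Gaussian band SD in the same units.
    """

    temperature_C: float = 24.0
    chloroquine_dim1_ug_ml: float = 0.0
    chloroquine_dim2_ug_ml: float = 7.5
    mobility_saturation_wr: float = 20.0
    migration_max: float = 100.0
    band_width: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chloroquine_dim1_ug_ml < 0 or self.chloroquine_dim2_ug_ml < 0:
            raise ValueError("chloroquine concentrations must be >= 0")
        if self.mobility_saturation_wr <= 0:
            raise ValueError("mobility_saturation_wr must be > 0")
        if self.band_width <= 0 or self.migration_max <= 0:
            raise ValueError("band_width and migration_max must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_topoisomers(
    plasmid: PlasmidSpec,
    center_writhe: float,
    spread: float,
    n_molecules: int,
    seed: int,
    nicked_fraction: float = 0.0,
) -> TopoisomerDistribution:
    """Sample a topoisomer ensemble around ``center_writhe``.

    Abundances are proportional to a Gaussian density over integer writhe
    (SD = ``spread``), multinomially sampled to ``n_molecules`` closed
    circles.  Deterministic given ``seed``.
    """
    if spread <= 0:
        raise ValueError("spread must be > 0")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    lo = math.floor(center_writhe - max(6.0 * spread, 1.0))
    hi = math.ceil(center_writhe + max(6.0 * spread, 1.0))
    ks = np.arange(lo, hi + 1)
    p = np.exp(-((ks - center_writhe) ** 2) / (2.0 * spread**2))
    p /= p.sum()
    counts = rng.multinomial(n_molecules, p)
    entries = tuple(
        (int(k), float(c)) for k, c in zip(ks, counts) if c > 0
    )
    return TopoisomerDistribution(
        plasmid=plasmid, entries=entries, nicked_fraction=nicked_fraction
    )


def calibrate_chloroquine_coefficient(
    supercoils_introduced: float, concentration_ug_ml: float, plasmid: PlasmidSpec
) -> float:
    """Unwinding coefficient u = supercoils / (concentration * N).

    One paired gel measurement (supercoils introduced at a known
    concentration on a known plasmid) fixes the linear unwinding model.
    """
    if concentration_ug_ml <= 0:
        raise ValueError("concentration must be > 0")
    return supercoils_introduced / (concentration_ug_ml * plasmid.length_bp)


def effective_writhe(
    writhe_native: float,
    plasmid: PlasmidSpec,
    gel: GelConditions,
    growth_temp_C: float,
    params: CorrectionParameters = CorrectionParameters(),
    dimension: int = 1,
) -> float:
    """Writhe the topoisomer exhibits under the gel's run conditions.

    Wr_eff = Wr_native + dWr_temp(growth -> gel) + u * c(dimension) * N.
    Affine in the native writhe, the chloroquine concentration and N.
    """
    if dimension not in (1, 2):
        raise ValueError("dimension must be 1 or 2")
    conc = gel.chloroquine_dim1_ug_ml if dimension == 1 else gel.chloroquine_dim2_ug_ml
    chl = params.chloroquine_unwinding_per_ug_ml_per_bp * conc * plasmid.length_bp
    if params.round_corrections:
        chl = float(round(chl))
    temp = temperature_writhe_shift(plasmid, growth_temp_C, gel.temperature_C, params)
    return writhe_native + temp + chl


def migrate(
    wr_eff: float, gel: GelConditions, saturation: float | None = None
) -> float:
    """Migration distance of a closed topoisomer, in gel units.

    position = migration_max * min(|wr_eff|, S) / S -- strictly increasing
    in |wr_eff| up to the saturation writhe S, constant beyond (the front
    band).  Relaxed and nicked species sit at the origin.
    """
    S = gel.mobility_saturation_wr if saturation is None else saturation
    return gel.migration_max * min(abs(wr_eff), S) / S


def dim2_saturation(
    plasmid: PlasmidSpec,
    gel: GelConditions,
    params: CorrectionParameters = CorrectionParameters(),
) -> float:
    """Saturation writhe used for the second dimension.

    The second-dimension chloroquine shifts every effective writhe by
    u*c2*N turns; widening the saturation threshold by the same amount keeps
    the whole arc range in the linear mobility regime, so the second
    dimension acts purely as an arc-separating (sign-resolving) axis.
    """
    shift = abs(
        params.chloroquine_unwinding_per_ug_ml_per_bp
        * gel.chloroquine_dim2_ug_ml
        * plasmid.length_bp
    )
    return gel.mobility_saturation_wr + shift


def profile_from_bands(
    positions: np.ndarray,
    abundances: np.ndarray,
    band_width: float,
    axis: np.ndarray | None = None,
    step: float = 0.2,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sum-of-Gaussians intensity profile for bands at ``positions``.

    Each band is a Gaussian of SD ``band_width`` whose *area* equals its
    abundance, so total profile area conserves total abundance.  Returns a
    two-column frame (position, intensity).
    """
    positions = np.asarray(positions, dtype=float)
    abundances = np.asarray(abundances, dtype=float)
    if axis is None:
        lo = positions.min() - 6.0 * band_width
        hi = positions.max() + 6.0 * band_width
        axis = np.arange(lo, hi + step, step)
    intensity = np.zeros_like(axis)
    norm = 1.0 / (band_width * math.sqrt(2.0 * math.pi))
    for pos, ab in zip(positions, abundances):
        intensity += ab * norm * np.exp(-((axis - pos) ** 2) / (2.0 * band_width**2))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity = intensity + rng.normal(0.0, noise_sd, size=axis.shape)
    return pd.DataFrame({"position": axis, "intensity": intensity})


def _effective_table(
    dist: TopoisomerDistribution,
    gel: GelConditions,
    growth_temp_C: float,
    params: CorrectionParameters,
) -> pd.DataFrame:
    rows = []
    s2 = dim2_saturation(dist.plasmid, gel, params)
    for w, a in dist.entries:
        e1 = effective_writhe(w, dist.plasmid, gel, growth_temp_C, params, dimension=1)
        e2 = effective_writhe(w, dist.plasmid, gel, growth_temp_C, params, dimension=2)
        rows.append(
            {
                "true_writhe": w,
                "abundance": a,
                "wr_eff_dim1": e1,
                "wr_eff_dim2": e2,
                "dimension1_position": migrate(e1, gel),
                "dimension2_position": migrate(e2, gel, saturation=s2),
            }
        )
    return pd.DataFrame(rows)


def render_gel(
    dist: TopoisomerDistribution,
    gel: GelConditions,
    growth_temp_C: float,
    params: CorrectionParameters = CorrectionParameters(),
    mode: str = "1D",
) -> pd.DataFrame:
    """Render the population under the gel conditions.

    mode="1D": first-dimension intensity profile, columns
    (position, intensity).  Bands are Gaussians of SD ``gel.band_width``
    with area proportional to abundance; Gaussian noise of SD
    ``gel.noise_sd`` is added, seeded by ``gel.seed``.

    mode="2D": spot table, one row per species, columns
    (dimension1_position, dimension2_position, intensity, true_writhe);
    the nicked species (if any) appears at the origin with NaN writhe.
    """
    if not dist.entries:
        raise ValueError("empty topoisomer distribution")
    table = _effective_table(dist, gel, growth_temp_C, params)
    if mode == "2D":
        spots = table.rename(columns={"abundance": "intensity"})[
            ["dimension1_position", "dimension2_position", "intensity", "true_writhe"]
        ]
        if dist.nicked_abundance > 0:
            nick = pd.DataFrame(
                {
                    "dimension1_position": [0.0],
                    "dimension2_position": [0.0],
                    "intensity": [dist.nicked_abundance],
                    "true_writhe": [np.nan],
                }
            )
            spots = pd.concat([spots, nick], ignore_index=True)
        return spots
    if mode != "1D":
        raise ValueError(f"mode must be '1D' or '2D', got {mode!r}")

    positions = table["dimension1_position"].to_numpy()
    abundances = table["abundance"].to_numpy()
    if dist.nicked_abundance > 0:
        positions = np.append(positions, 0.0)
        abundances = np.append(abundances, dist.nicked_abundance)
    # Fixed axis spanning the whole lane so profiles are comparable
    lo = -6.0 * gel.band_width
    hi = gel.migration_max + 6.0 * gel.band_width
    axis = np.arange(lo, hi + 0.2, 0.2)
    rng = np.random.default_rng(gel.seed)
    return profile_from_bands(
        positions,
        abundances,
        gel.band_width,
        axis=axis,
        noise_sd=gel.noise_sd,
        rng=rng,
    )


def plot_gel_2d(spots: pd.DataFrame, path: str) -> None:
    """Save a scatter rendering of a 2D spot table as PNG (visual QC only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sizes = 200.0 * spots["intensity"] / spots["intensity"].max()
    ax.scatter(
        spots["dimension1_position"], spots["dimension2_position"], s=sizes, c="k"
    )
    ax.set_xlabel("dimension 1 migration")
    ax.set_ylabel("dimension 2 migration")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
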