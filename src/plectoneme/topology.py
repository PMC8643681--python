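"""Pure arithmetic of closed-circular DNA topology.

The topological state of a covalently closed circular plasmid is described
by the linking number Lk = Tw + Wr, where Tw (twist) is the helical winding
of the two strands about the duplex axis and Wr (writhe) is the coiling of
the axis in space.  Gel electrophoresis of topoisomer ladders resolves
integer steps in Wr; the supercoiling density sigma = Wr / Tw normalises the
linking difference so it can be compared across plasmids of different size.

Two systematic effects separate the writhe read off a chloroquine gel from
the writhe the plasmid carried in the living cell:

* intercalation -- chloroquine locally unwinds the helix, lowering Tw and
  (at constant Lk) pushing Wr toward positive values;
* temperature -- the helical pitch increases with temperature, so cooling a
  plasmid from growth temperature to the electrophoresis temperature raises
  Tw and pushes Wr negative; the helix-angle change is taken as
  0.011 degrees per degree Celsius per base pair.

This module holds only the arithmetic: no file I/O, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_HELICAL_REPEAT_BP",
    "DEFAULT_TEMP_COEFFICIENT",
    "DEFAULT_CHLOROQUINE_COEFFICIENT",
    "PlasmidSpec",
    "CorrectionParameters",
    "SupercoilingResult",
    "twist",
    "linking_number",
    "temperature_writhe_shift",
    "chloroquine_shift_from_gels",
    "native_writhe",
    "supercoiling_density",
]

#: B-form helical repeat under standard conditions, bp per turn.
DEFAULT_HELICAL_REPEAT_BP = 10.5

#: Magnitude of the helix-angle change, degrees per deg C per bp.
DEFAULT_TEMP_COEFFICIENT = 0.011

#: Unwinding per (ug/ml chloroquine x bp), in turns.  Calibrated from the
#: one available measurement: 19 positive supercoils introduced into a
#: 5455 bp plasmid by 1.5 ug/ml chloroquine in the first gel dimension.
DEFAULT_CHLOROQUINE_COEFFICIENT = 19.0 / (1.5 * 5455.0)


@dataclass(frozen=True)
class PlasmidSpec:
    """A circular DNA molecule: identity, size and helical repeat.

    Parameters
    ----------
    name : str
        Label for reports.
    length_bp : int
        Plasmid length N in base pairs (>= 100).
    helical_repeat : float
        Base pairs per helix turn h (> 0), default 10.5.
    """

    name: str
    length_bp: int
    helical_repeat: float = DEFAULT_HELICAL_REPEAT_BP

    def __post_init__(self) -> None:
        if self.length_bp < 100:
            raise ValueError(f"length_bp must be >= 100, got {self.length_bp}")
        if self.helical_repeat <= 0:
            raise ValueError(
                f"helical_repeat must be > 0, got {self.helical_repeat}"
            )

    @property
    def twist(self) -> float:
        """Relaxed twist Tw = N / h, in turns (equals Lk0)."""
        return self.length_bp / self.helical_repeat


@dataclass(frozen=True)
class CorrectionParameters:
    """Coefficients converting physical conditions into writhe corrections.

    ``round_corrections`` rounds whole-supercoil corrections to the nearest
    integer, matching how supercoils are counted on a gel (bands are integer
    steps in Wr).
    """

    temp_coefficient_deg_per_C_per_bp: float = DEFAULT_TEMP_COEFFICIENT
    degrees_per_turn: float = 360.0
    chloroquine_unwinding_per_ug_ml_per_bp: float = DEFAULT_CHLOROQUINE_COEFFICIENT
    round_corrections: bool = True

    def __post_init__(self) -> None:
        if self.temp_coefficient_deg_per_C_per_bp < 0:
            raise ValueError("temp_coefficient must be >= 0")
        if self.degrees_per_turn != 360.0:
            raise ValueError("degrees_per_turn is fixed at 360")


def twist(plasmid: PlasmidSpec) -> float:
    """Relaxed twist Tw = N / h of *plasmid*, in helix turns."""
    return plasmid.twist


def linking_number(plasmid: PlasmidSpec, wr: float) -> float:
    """Linking number Lk = Tw + Wr, with Tw at its relaxed reference.

    With that reference, the linking difference dLk = Lk - Lk0 equals the
    writhe, which is what topoisomer ladders count.
    """
    return plasmid.twist + wr


def temperature_writhe_shift(
    plasmid: PlasmidSpec,
    t_growth_C: float,
    t_gel_C: float,
    params: CorrectionParameters = CorrectionParameters(),
) -> float:
    """Supercoils introduced by bringing the plasmid from growth to gel temperature.

    Cooling tightens the helix (raising Tw at constant Lk), so the writhe
    shift is negative when ``t_gel_C < t_growth_C``:

        dWr_temp = (t_gel - t_growth) * c_T * N / 360

    Rounded to the nearest whole supercoil when
    ``params.round_corrections`` is true.
    """
    raw = (
        (t_gel_C - t_growth_C)
        * params.temp_coefficient_deg_per_C_per_bp
        * plasmid.length_bp
        / params.degrees_per_turn
    )
    return float(round(raw)) if params.round_corrections else raw


def chloroquine_shift_from_gels(wr_with_chl: float, wr_without_chl: float) -> float:
    """Supercoils introduced by intercalation, from a paired gel measurement.

    Both writhes must come from the same sample at the same gel temperature;
    the only difference between the two first-dimension runs is the
    intercalator, so dWr_chl = Wr(with) - Wr(without).
    """
    return wr_with_chl - wr_without_chl


def native_writhe(
    wr_apparent: float, delta_wr_chl: float, delta_wr_temp: float
) -> float:
    """In-vivo writhe at growth temperature from the gel-apparent writhe.

    Subtracts both systematic shifts from the major topoisomer's apparent
    writhe (read on the chloroquine-containing first dimension):

        Wr_native = Wr_apparent - dWr_chl - dWr_temp

    ``delta_wr_temp`` is negative for cooling, so for a plasmid grown hot
    and run cold the temperature term adds supercoils back.
    """
    return wr_apparent - delta_wr_chl - delta_wr_temp


def supercoiling_density(wr_native: float, plasmid: PlasmidSpec) -> float:
    """Supercoiling density sigma = Wr_native / Tw (dimensionless).

    Negative sigma = underwound (negatively supercoiled), positive =
    overwound.  Summaries conventionally report sigma to 4 decimal places;
    this function returns full precision.
    """
    return wr_native / plasmid.twist


@dataclass(frozen=True)
class SupercoilingResult:
    """Native writhe, twist and sigma with the full correction breakdown.

    Keeps every intermediate of the band-counting calculation so a result
    can be audited:  sigma * twist == wr_native and
    wr_apparent == wr_native + delta_wr_chloroquine + delta_wr_temperature.
    """

    plasmid: PlasmidSpec
    wr_apparent: float
    delta_wr_chloroquine: float
    delta_wr_temperature: float
    wr_native: float = field(init=False)
    twist: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        wr = native_writhe(
            self.wr_apparent, self.delta_wr_chloroquine, self.delta_wr_temperature
        )
        object.__setattr__(self, "wr_native", wr)
        object.__setattr__(self, "twist", self.plasmid.twist)
        object.__setattr__(self, "sigma", supercoiling_density(wr, self.plasmid))

    @property
    def sigma_rounded(self) -> float:
        """sigma at the conventional 4-decimal reporting precision."""
        return round(self.sigma, 4)

    def as_dict(self) -> dict:
        return {
            "plasmid": self.plasmid.name,
            "length_bp": self.plasmid.length_bp,
            "helical_repeat": self.plasmid.helical_repeat,
            "twist": self.twist,
            "wr_apparent": self.wr_apparent,
            "delta_wr_chloroquine": self.delta_wr_chloroquine,
            "delta_wr_temperature": self.delta_wr_temperature,
            "wr_native": self.wr_native,
            "sigma": self.sigma,
            "sigma_rounded": self.sigma_rounded,
        }
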