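"""Trial layout, treatment coding and fertiliser schedule.

The experiment crosses three cultivation types (grass monoculture, legume
monoculture, grass-legume mixture) with a 2x2 factorial of nitrogen and
phosphorus supply, giving 12 treatments.  The layout is a latinized, resolved
incomplete-block design: each replicate block contains 4 main units (one per
nutrient combination), each main unit 3 consecutive pots (one per cultivation
type), and each pot two half-pots, the analysis unit.  Mixture pots carry
grass on one half and legume on the other; monoculture pots carry the same
species on both halves.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cultivation",
    "Species",
    "Treatment",
    "FertiliserSchedule",
    "TrialDesign",
    "NUTRIENT_COMBOS",
    "NUTRIENT_TOTALS",
    "BASELINE_DAP",
    "TOPUP_DAP",
    "BASELINE_N_MG",
    "BASELINE_P_MG",
    "all_treatments",
    "generate_design",
    "fertiliser_schedule",
    "validate_design",
]


class Cultivation(str, enum.Enum):
    GRASS_MONO = "grass-mono"
    LEGUME_MONO = "legume-mono"
    MIXTURE = "mixture"


class Species(str, enum.Enum):
    GRASS = "grass"
    LEGUME = "legume"


#: Nutrient combinations in canonical order; levels are "L" (low) / "H" (high).
NUTRIENT_COMBOS: tuple[tuple[str, str], ...] = (
    ("L", "L"),
    ("H", "H"),
    ("H", "L"),
    ("L", "H"),
)

#: Total (N mg, P mg) added per pot by the end of the fertilisation schedule.
NUTRIENT_TOTALS: dict[tuple[str, str], tuple[float, float]] = {
    ("H", "H"): (99.0, 33.0),
    ("H", "L"): (99.0, 11.0),
    ("L", "H"): (33.0, 33.0),
    ("L", "L"): (33.0, 11.0),
}

BASELINE_DAP = 16
TOPUP_DAP = 35
BASELINE_N_MG = 33.0
BASELINE_P_MG = 11.0


@dataclass(frozen=True)
class Treatment:
    """One of the 12 experimental treatments."""

    cultivation: Cultivation
    nitrogen: str  # "L" or "H"
    phosphorus: str  # "L" or "H"

    def __post_init__(self) -> None:
        if self.nitrogen not in ("L", "H"):
            raise ValueError(f"nitrogen level must be 'L' or 'H', got {self.nitrogen!r}")
        if self.phosphorus not in ("L", "H"):
            raise ValueError(f"phosphorus level must be 'L' or 'H', got {self.phosphorus!r}")

    @property
    def nutrient_label(self) -> str:
        return f"{self.nitrogen}N{self.phosphorus}P"


def all_treatments() -> list[Treatment]:
    """The full crossing: 3 cultivations x 4 nutrient combinations."""
    return [
        Treatment(c, n, p)
        for c in Cultivation
        for (n, p) in NUTRIENT_COMBOS
    ]


@dataclass(frozen=True)
class FertiliserSchedule:
    """Per-pot nutrient addition events (DAP, N mg, P mg) and their totals."""

    events: tuple[tuple[int, float, float], ...]
    total_n: float
    total_p: float

    @property
    def np_ratio(self) -> float:
        return self.total_n / self.total_p


def fertiliser_schedule(treatment: Treatment) -> FertiliserSchedule:
    """Fertiliser events for a treatment.

    All pots receive the low-N low-P baseline (33 mg N, 11 mg P) at DAP 16;
    at DAP 35 a top-up raises the totals to the treatment target.  Low-low
    pots receive a zero-valued top-up.  Nutrients are applied at pot level,
    so the schedule is independent of cultivation.
    """
    total_n, total_p = NUTRIENT_TOTALS[(treatment.nitrogen, treatment.phosphorus)]
    events = (
        (BASELINE_DAP, BASELINE_N_MG, BASELINE_P_MG),
        (TOPUP_DAP, total_n - BASELINE_N_MG, total_p - BASELINE_P_MG),
    )
    return FertiliserSchedule(events=events, total_n=total_n, total_p=total_p)


@dataclass
class TrialDesign:
    """Randomized layout, one row per half-pot.

    The table has columns: replicate, main_unit (1-based within replicate),
    pot_id (zero-padded, stable), side ("E"/"W"), greenhouse_side ("E"/"W"),
    species, cultivation, nitrogen, phosphorus.
    """

    table: pd.DataFrame
    n_reps: int
    seed: int

    COLUMNS = (
        "replicate",
        "main_unit",
        "pot_id",
        "half_pot_id",
        "side",
        "greenhouse_side",
        "species",
        "cultivation",
        "nitrogen",
        "phosphorus",
    )

    @property
    def n_pots(self) -> int:
        return self.table["pot_id"].nunique()

    @property
    def n_half_pots(self) -> int:
        return len(self.table)

    def pots(self) -> pd.DataFrame:
        """Pot-level view (one row per pot)."""
        return (
            self.table.drop(columns=["half_pot_id", "side", "species"])
            .drop_duplicates("pot_id")
            .reset_index(drop=True)
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_reps: int | None = None, seed: int = -1) -> "TrialDesign":
        table = pd.read_csv(path, dtype={"pot_id": str, "half_pot_id": str})
        if n_reps is None:
            n_reps = int(table["replicate"].nunique())
        return cls(table=table, n_reps=n_reps, seed=seed)


def _latinized_nutrient_order(rng: np.random.Generator, n_reps: int) -> list[list[tuple[str, str]]]:
    """Per-replicate orderings of the 4 nutrient combos over main-unit positions.

    Greedy column-balance constraint: each combination appears in each
    within-replicate position at most ceil(n_reps / 4) times, preserving the
    blocking semantics of a latinized layout without an optimal-design search.
    """
    cap = math.ceil(n_reps / 4)
    counts = {pos: {combo: 0 for combo in NUTRIENT_COMBOS} for pos in range(4)}
    orders: list[list[tuple[str, str]]] = []
    for _ in range(n_reps):
        for _attempt in range(200):
            perm = [NUTRIENT_COMBOS[i] for i in rng.permutation(4)]
            if all(counts[pos][combo] < cap for pos, combo in enumerate(perm)):
                break
        for pos, combo in enumerate(perm):
            counts[pos][combo] += 1
        orders.append(perm)
    return orders


def generate_design(n_reps: int, seed: int) -> TrialDesign:
    """Generate a randomized resolved design with ``n_reps`` replicate blocks.

    Each replicate contains every treatment exactly once.  Nutrient
    combinations are randomized over the 4 main units (latinized column
    balance), cultivations over the 3 pots of each main unit, and the grass
    half of each mixture pot over the two sides.  Greenhouse side is assigned
    positionally: main units 1-2 east, 3-4 west.  Deterministic for a fixed
    seed.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    nutrient_orders = _latinized_nutrient_order(rng, n_reps)
    cultivations = list(Cultivation)

    rows = []
    pot_counter = 0
    n_pots_total = 12 * n_reps
    pad = max(3, len(str(n_pots_total)))
    for rep in range(1, n_reps + 1):
        for mu_pos in range(4):
            nitrogen, phosphorus = nutrient_orders[rep - 1][mu_pos]
            greenhouse_side = "E" if mu_pos < 2 else "W"
            cult_order = [cultivations[i] for i in rng.permutation(3)]
            for cult in cult_order:
                pot_counter += 1
                pot_id = f"P{pot_counter:0{pad}d}"
                if cult is Cultivation.GRASS_MONO:
                    species_by_side = {"E": Species.GRASS, "W": Species.GRASS}
                elif cult is Cultivation.LEGUME_MONO:
                    species_by_side = {"E": Species.LEGUME, "W": Species.LEGUME}
                else:
                    grass_side = "E" if rng.random() < 0.5 else "W"
                    species_by_side = {
                        "E": Species.GRASS if grass_side == "E" else Species.LEGUME,
                        "W": Species.LEGUME if grass_side == "E" else Species.GRASS,
                    }
                for side in ("E", "W"):
                    rows.append(
                        {
                            "replicate": rep,
                            "main_unit": mu_pos + 1,
                            "pot_id": pot_id,
                            "half_pot_id": f"{pot_id}{side}",
                            "side": side,
                            "greenhouse_side": greenhouse_side,
                            "species": species_by_side[side].value,
                            "cultivation": cult.value,
                            "nitrogen": nitrogen,
                            "phosphorus": phosphorus,
                        }
                    )
    table = pd.DataFrame(rows, columns=TrialDesign.COLUMNS)
    return TrialDesign(table=table, n_reps=n_reps, seed=seed)


def validate_design(design: TrialDesign) -> list[str]:
    """Check the structural invariants; returns one message per violation.

    Never raises: a malformed design yields a non-empty list.
    """
    violations: list[str] = []
    t = design.table
    n_reps = t["replicate"].nunique()

    if design.n_pots != 12 * n_reps:
        violations.append(
            f"pot-count: expected {12 * n_reps} pots for {n_reps} replicates, found {design.n_pots}"
        )
    if design.n_half_pots != 24 * n_reps:
        violations.append(
            f"half-pot-count: expected {24 * n_reps} half-pots, found {design.n_half_pots}"
        )

    # resolved design: every replicate carries all 12 treatments exactly once
    pots = t.drop_duplicates("pot_id")
    for rep, grp in pots.groupby("replicate"):
        combos = set(zip(grp["cultivation"], grp["nitrogen"], grp["phosphorus"]))
        expected = {
            (c.value, n, p) for c in Cultivation for (n, p) in NUTRIENT_COMBOS
        }
        missing = expected - combos
        if missing or len(grp) != 12:
            violations.append(
                f"unresolved-replicate: replicate {rep} does not contain each treatment exactly once"
                + (f" (missing {sorted(missing)})" if missing else "")
            )

    # species assignment per cultivation
    for pot_id, grp in t.groupby("pot_id"):
        cult = grp["cultivation"].iloc[0]
        species = sorted(grp["species"])
        if len(grp) != 2:
            violations.append(f"half-pot-structure: pot {pot_id} has {len(grp)} halves")
            continue
        ok = {
            Cultivation.GRASS_MONO.value: ["grass", "grass"],
            Cultivation.LEGUME_MONO.value: ["legume", "legume"],
            Cultivation.MIXTURE.value: ["grass", "legume"],
        }[cult]
        if species != ok:
            violations.append(
                f"species-assignment: pot {pot_id} ({cult}) carries species {species}"
            )

    # each main unit has one nutrient combo; each replicate all four
    for (rep, mu), grp in t.groupby(["replicate", "main_unit"]):
        if grp[["nitrogen", "phosphorus"]].drop_duplicates().shape[0] != 1:
            violations.append(
                f"main-unit-nutrients: replicate {rep} main unit {mu} mixes nutrient combinations"
            )
    return violations
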