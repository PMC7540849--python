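"""Simulator for the grass-legume mixture experiment.

Generates the complete data bundle the analysis pipeline consumes — daily
view-level plant pixel counts, harvest dry biomass and shoot/soil nutrients —
with the statistical structure the mixed model assumes, so every downstream
stage is testable without real greenhouse data.

Growth model: each half-pot follows a 3-parameter logistic curve

    PSA_true(t) = A / (1 + exp(-r (t - t0)))

on the imaging window DAP 28-70 (43 consecutive days).  A is parametrized
through the monoculture endpoint targets sPSA(70) per (species, N, P) cell —
the defaults reproduce the published treatment-mean magnitudes — and mixture
halves multiply A (and optionally r) by species-specific facilitation
factors, so the configured factor is also the expected relative yield.
Replicate, main-unit and pot random effects act multiplicatively (log scale)
on A; day-to-day measurement noise is multiplicative lognormal on the daily
total, which is then split equally over the three camera views.  A half-pot
residual effect with species x nitrogen group-specific standard deviation
(harvest scale, kpixels) is ramped in linearly over the window, so it passes
through the spline smoother onto the endpoint and gives the heteroscedastic
residual model a true signal to detect.

Harvest biomass is a linear proxy of the true endpoint
(AGB = c_species * PSA_true(70) + noise); shoot and soil nutrient
concentrations are drawn around configurable treatment-cell means
(defaults follow the published shoot-nutrient treatment means).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment_design import Cultivation, TrialDesign

__all__ = [
    "GrowthParams",
    "AttritionRules",
    "SimulatedDataset",
    "default_params",
    "simulate",
    "apply_attrition",
    "published_attrition_rules",
    "IMAGING_DAYS",
]

#: imaging window: 43 consecutive days ending at final harvest
IMAGING_DAYS = tuple(range(28, 71))

VIEWS = ("top", "side1", "side2")

Cell = tuple[str, str, str]  # (species, nitrogen, phosphorus)


@dataclass
class GrowthParams:
    """All simulator parameters.  Cell keys are (species, N-level, P-level)."""

    mono_endpoint: dict[Cell, float]  # target noiseless sPSA(70), kpixels
    rate: dict[Cell, float]  # logistic rate r, day^-1
    t0: dict[Cell, float]  # inflection day, DAP
    facilitation_a: dict[Cell, float]  # asymptote multiplier for mixture halves
    facilitation_r: dict[Cell, float]  # rate multiplier for mixture halves
    rate_jitter_sd: float = 0.03  # half-pot lognormal jitter on r (log scale)
    day_noise_sd: float = 0.12  # day-to-day lognormal noise (log scale)
    sd_rep: float = 0.05  # replicate random effect, log scale
    sd_mainunit: float = 0.06  # main-unit random effect, log scale
    sd_pot: float = 0.06  # pot random effect, log scale
    resid_sd: dict[tuple[str, str], float] = field(
        default_factory=dict
    )  # (species, N) -> half-pot residual sd, kpixels
    proxy_slope: dict[str, float] = field(default_factory=dict)  # g per kpixel
    proxy_sd: dict[str, float] = field(default_factory=dict)  # g, per half-pot
    proxy_pot_sd: float = 0.0  # g, harvest error shared by a pot's two halves
    shoot_n: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    # (species, cultivation mono/mix, N, P) -> mg g^-1
    shoot_p: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    shoot_n_sd: dict[str, float] = field(default_factory=dict)  # per species
    shoot_p_sd: dict[str, float] = field(default_factory=dict)
    soil_n: dict[str, float] = field(default_factory=dict)  # N level -> mg kg^-1
    soil_p: dict[str, float] = field(default_factory=dict)  # P level -> mg kg^-1
    soil_n_sd: float = 1.0
    soil_p_sd: float = 0.8
    days: tuple[int, ...] = IMAGING_DAYS

    def validate(self) -> None:
        for cell, a in self.mono_endpoint.items():
            if a <= 0:
                raise ValueError(f"endpoint target must be > 0 for {cell}")
        for d in (self.rate, self.facilitation_a, self.facilitation_r):
            for cell, v in d.items():
                if v <= 0:
                    raise ValueError(f"positive value required, got {v} for {cell}")
        for name in ("rate_jitter_sd", "day_noise_sd", "sd_rep", "sd_mainunit", "sd_pot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_params() -> GrowthParams:
    """Defaults emulating the published study's magnitudes.

    Monoculture endpoint targets and facilitation multipliers follow the
    published treatment means of sPSA(70) and their mixture/monoculture
    ratios; shoot nutrient means follow the published shoot N and P tables.
    Growth rates and inflection days encode the reported qualitative
    dynamics: grass grows faster than legume and, without added N, saturates
    before the final interval; legume growth is slower and P-responsive.
    """
    g, l = "grass", "legume"
    mono = {
        (g, "H", "H"): 527.9,
        (g, "L", "H"): 200.8,
        (g, "H", "L"): 493.3,
        (g, "L", "L"): 200.4,
        (l, "H", "H"): 548.6,
        (l, "L", "H"): 548.6,
        (l, "H", "L"): 436.6,
        (l, "L", "L"): 436.6,
    }
    fac_a = {
        (g, "H", "H"): 1.117,
        (g, "L", "H"): 1.790,
        (g, "H", "L"): 1.297,
        (g, "L", "L"): 1.446,
        (l, "H", "H"): 1.087,
        (l, "L", "H"): 1.087,
        (l, "H", "L"): 1.109,
        (l, "L", "L"): 1.109,
    }
    rate = {}
    t0 = {}
    for (sp, n, p) in mono:
        if sp == g:
            rate[(sp, n, p)] = 0.16 if n == "H" else 0.13
            t0[(sp, n, p)] = 45.0 if n == "H" else 38.0
        else:
            rate[(sp, n, p)] = 0.115 if p == "H" else 0.100
            t0[(sp, n, p)] = 50.0
    fac_r = {cell: 1.0 for cell in mono}

    shoot_n = {}
    for n in ("H", "L"):
        for p in ("H", "L"):
            shoot_n[(g, "mono", n, p)] = 14.34 if n == "H" else 7.00
            shoot_n[(g, "mix", n, p)] = 18.96 if n == "H" else 9.18
    legume_n = {("H", "H"): 31.06, ("L", "H"): 32.58, ("H", "L"): 29.17, ("L", "L"): 26.87}
    for (n, p), v in legume_n.items():
        shoot_n[(l, "mono", n, p)] = v
        shoot_n[(l, "mix", n, p)] = v

    grass_p_mono = {("H", "H"): 3.48, ("L", "H"): 3.09, ("H", "L"): 1.17, ("L", "L"): 1.84}
    grass_p_mix = {("H", "H"): 3.75, ("L", "H"): 3.36, ("H", "L"): 1.45, ("L", "L"): 2.12}
    shoot_p = {}
    for (n, p), v in grass_p_mono.items():
        shoot_p[(g, "mono", n, p)] = v
    for (n, p), v in grass_p_mix.items():
        shoot_p[(g, "mix", n, p)] = v
    for n in ("H", "L"):
        for p in ("H", "L"):
            v = 1.98 if p == "H" else 1.27
            shoot_p[(l, "mono", n, p)] = v
            shoot_p[(l, "mix", n, p)] = v

    return GrowthParams(
        mono_endpoint=mono,
        rate=rate,
        t0=t0,
        facilitation_a=fac_a,
        facilitation_r=fac_r,
        resid_sd={(g, "L"): 14.0, (g, "H"): 30.0, (l, "L"): 20.0, (l, "H"): 26.0},
        proxy_slope={g: 0.009, l: 0.008},
        proxy_sd={g: 0.45, l: 0.05},
        proxy_pot_sd=0.38,
        shoot_n=shoot_n,
        shoot_p=shoot_p,
        shoot_n_sd={g: 1.4, l: 2.6},
        shoot_p_sd={g: 0.28, l: 0.20},
        soil_n={"H": 10.0, "L": 3.5},
        soil_p={"H": 9.0, "L": 3.0},
    )


@dataclass
class SimulatedDataset:
    """The full simulated bundle plus the generating truth."""

    design: TrialDesign
    psa: pd.DataFrame  # half_pot_id, DAP, view, kpixels
    harvest: pd.DataFrame  # half_pot_id, AGB
    nutrients: pd.DataFrame  # half_pot_id, pot_id, shoot_n, shoot_p, soil_n, soil_p
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(outdir / "design.csv")
        self.psa.to_csv(outdir / "psa.csv", index=False)
        self.harvest.to_csv(outdir / "harvest.csv", index=False)
        self.nutrients.to_csv(outdir / "nutrients.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _logistic(t: np.ndarray, A: float, r: float, t0: float) -> np.ndarray:
    return A / (1.0 + np.exp(-r * (t - t0)))


def simulate(design: TrialDesign, params: GrowthParams, seed: int) -> SimulatedDataset:
    """Simulate the experiment on a given layout; reproducible for a seed."""
    params.validate()
    table = design.table
    species_in_design = set(table["species"].unique())
    species_in_params = {c[0] for c in params.mono_endpoint}
    if not species_in_design <= species_in_params:
        raise ValueError(
            f"design species {sorted(species_in_design)} not covered by params "
            f"{sorted(species_in_params)}"
        )
    rng = np.random.default_rng(seed)
    days = np.asarray(params.days, dtype=float)
    t_end = days[-1]
    ramp = (days - days[0]) / (days[-1] - days[0])

    u_rep = {r: rng.normal(0.0, params.sd_rep) for r in sorted(table["replicate"].unique())}
    mus = sorted(set(zip(table["replicate"], table["main_unit"])))
    u_mu = {k: rng.normal(0.0, params.sd_mainunit) for k in mus}
    u_pot = {p: rng.normal(0.0, params.sd_pot) for p in sorted(table["pot_id"].unique())}

    psa_rows = []
    harvest_rows = []
    nutrient_rows = []
    truth_units = {}
    soil_by_pot: dict[str, tuple[float, float]] = {}
    pot_proxy_err: dict[str, float] = {}

    for row in table.itertuples(index=False):
        sp, n, p = row.species, row.nitrogen, row.phosphorus
        cell = (sp, n, p)
        is_mix = row.cultivation == Cultivation.MIXTURE.value
        cultivation = "mix" if is_mix else "mono"
        r_base = params.rate[cell] * (params.facilitation_r[cell] if is_mix else 1.0)
        t0 = params.t0[cell]
        r_hp = r_base * np.exp(rng.normal(0.0, params.rate_jitter_sd))
        u = u_rep[row.replicate] + u_mu[(row.replicate, row.main_unit)] + u_pot[row.pot_id]
        target = params.mono_endpoint[cell] * (params.facilitation_a[cell] if is_mix else 1.0)
        frac = 1.0 / (1.0 + np.exp(-r_base * (t_end - t0)))
        A = target * np.exp(u) / frac
        delta = rng.normal(0.0, params.resid_sd.get((sp, n), 0.0))

        curve = _logistic(days, A, r_hp, t0) + ramp * delta
        curve = np.maximum(curve, 1e-3)
        noise = np.exp(rng.normal(0.0, params.day_noise_sd, size=days.size))
        observed = curve * noise
        for d, tot in zip(params.days, observed):
            for view in VIEWS:
                psa_rows.append((row.half_pot_id, d, view, tot / 3.0))

        true70 = float(curve[-1])
        if row.pot_id not in pot_proxy_err:
            pot_proxy_err[row.pot_id] = rng.normal(0.0, params.proxy_pot_sd)
        agb = (
            params.proxy_slope[sp] * true70
            + pot_proxy_err[row.pot_id]
            + rng.normal(0.0, params.proxy_sd[sp])
        )
        harvest_rows.append((row.half_pot_id, max(agb, 1e-3)))

        if row.pot_id not in soil_by_pot:
            soil_by_pot[row.pot_id] = (
                max(params.soil_n[n] + rng.normal(0.0, params.soil_n_sd), 0.05),
                max(params.soil_p[p] + rng.normal(0.0, params.soil_p_sd), 0.05),
            )
        soil_n, soil_p = soil_by_pot[row.pot_id]
        shoot_n = max(
            params.shoot_n[(sp, cultivation, n, p)]
            + rng.normal(0.0, params.shoot_n_sd[sp]),
            0.1,
        )
        shoot_p = max(
            params.shoot_p[(sp, cultivation, n, p)]
            + rng.normal(0.0, params.shoot_p_sd[sp]),
            0.05,
        )
        nutrient_rows.append((row.half_pot_id, row.pot_id, shoot_n, shoot_p, soil_n, soil_p))
        truth_units[row.half_pot_id] = {
            "A": float(A),
            "r": float(r_hp),
            "t0": float(t0),
            "delta": float(delta),
            "true_psa70": true70,
            "u_pot": float(u_pot[row.pot_id]),
        }

    psa = pd.DataFrame(psa_rows, columns=["half_pot_id", "DAP", "view", "kpixels"])
    harvest = pd.DataFrame(harvest_rows, columns=["half_pot_id", "AGB"])
    nutrients = pd.DataFrame(
        nutrient_rows,
        columns=["half_pot_id", "pot_id", "shoot_n", "shoot_p", "soil_n", "soil_p"],
    )
    truth = {
        "seed": seed,
        "random_effects": {
            "replicate": {str(k): v for k, v in u_rep.items()},
            "mainunit": {f"{k[0]}:{k[1]}": v for k, v in u_mu.items()},
            "pot": u_pot,
        },
        "units": truth_units,
        "params": {
            "day_noise_sd": params.day_noise_sd,
            "sd_mainunit": params.sd_mainunit,
            "sd_pot": params.sd_pot,
            "resid_sd": {f"{k[0]}:{k[1]}": v for k, v in params.resid_sd.items()},
            "facilitation_a": {f"{k[0]}:{k[1]}{k[2]}": v for k, v in params.facilitation_a.items()},
            "mono_endpoint": {f"{k[0]}:{k[1]}{k[2]}": v for k, v in params.mono_endpoint.items()},
        },
    }
    return SimulatedDataset(design=design, psa=psa, harvest=harvest, nutrients=nutrients, truth=truth)


@dataclass
class AttritionRules:
    """Units to drop from the harvest/nutrient endpoints (imaging retained)."""

    dead_pots: list[str] = field(default_factory=list)
    clerical_half_pots: list[str] = field(default_factory=list)  # harvest + nutrients
    nutrient_only_half_pots: list[str] = field(default_factory=list)
    random_rate: float = 0.0
    random_seed: int = 0


def published_attrition_rules(design: TrialDesign) -> AttritionRules:
    """The published exclusion pattern, mapped onto a simulated layout.

    One grass-monoculture LNLP pot dies (2 half-pots); one half-pot each in
    the LNLP and LNHP grass monocultures is dropped for suspected clerical
    error (harvest and nutrients); two further half-pots (HNLP legume
    monoculture, LNHP grass monoculture) are dropped from the nutrient
    tables only.  Units are chosen deterministically as the first matching
    units in layout order.
    """
    t = design.table

    def first_pot(cult: str, n: str, p: str, exclude: set[str]) -> str:
        sel = t[
            (t["cultivation"] == cult)
            & (t["nitrogen"] == n)
            & (t["phosphorus"] == p)
            & (~t["pot_id"].isin(exclude))
        ]
        if sel.empty:
            raise ValueError(f"no pot matches ({cult}, {n}N{p}P)")
        return str(sel["pot_id"].iloc[0])

    dead = first_pot("grass-mono", "L", "L", set())
    clerical_lnlp_pot = first_pot("grass-mono", "L", "L", {dead})
    clerical_lnhp_pot = first_pot("grass-mono", "L", "H", set())
    nutrient_hnlp_pot = first_pot("legume-mono", "H", "L", set())
    nutrient_lnhp_pot = first_pot("grass-mono", "L", "H", {clerical_lnhp_pot})

    def first_half(pot: str) -> str:
        return str(t.loc[t["pot_id"] == pot, "half_pot_id"].iloc[0])

    return AttritionRules(
        dead_pots=[dead],
        clerical_half_pots=[first_half(clerical_lnlp_pot), first_half(clerical_lnhp_pot)],
        nutrient_only_half_pots=[first_half(nutrient_hnlp_pot), first_half(nutrient_lnhp_pot)],
    )


def apply_attrition(
    data: SimulatedDataset, rules: AttritionRules
) -> tuple[SimulatedDataset, dict]:
    """Drop harvest/nutrient rows per the rules; imaging data are never cut.

    Returns the filtered dataset and a count log.  Raises on a rule that
    names an unknown pot or half-pot.
    """
    t = data.design.table
    known_pots = set(t["pot_id"])
    known_halves = set(t["half_pot_id"])
    for pot in rules.dead_pots:
        if pot not in known_pots:
            raise ValueError(f"attrition rule references unknown pot {pot!r}")
    for hp in rules.clerical_half_pots + rules.nutrient_only_half_pots:
        if hp not in known_halves:
            raise ValueError(f"attrition rule references unknown half-pot {hp!r}")

    drop_harvest = set(
        t.loc[t["pot_id"].isin(rules.dead_pots), "half_pot_id"]
    ) | set(rules.clerical_half_pots)
    if rules.random_rate > 0:
        rng = np.random.default_rng(rules.random_seed)
        extra = [hp for hp in sorted(known_halves - drop_harvest) if rng.random() < rules.random_rate]
        drop_harvest |= set(extra)
    drop_nutrients = drop_harvest | set(rules.nutrient_only_half_pots)

    out = SimulatedDataset(
        design=data.design,
        psa=data.psa,
        harvest=data.harvest[~data.harvest["half_pot_id"].isin(drop_harvest)].reset_index(drop=True),
        nutrients=data.nutrients[~data.nutrients["half_pot_id"].isin(drop_nutrients)].reset_index(drop=True),
        truth=copy.deepcopy(data.truth),
    )
    log = {
        "harvest_before": len(data.harvest),
        "harvest_removed": int(data.harvest["half_pot_id"].isin(drop_harvest).sum()),
        "harvest_after": len(out.harvest),
        "nutrients_before": len(data.nutrients),
        "nutrients_removed": int(data.nutrients["half_pot_id"].isin(drop_nutrients).sum()),
        "nutrients_after": len(out.nutrients),
    }
    return out, log
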