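"""Relative yields, relative yield totals and the yield-ratio suite.

For each nutrient treatment, with species-level yields (estimated marginal
means of sPSA at the final day, or raw cell means) the relative yield of a
species is RY_i = Y_i(mix) / Y_i(mono), and the relative yield total is
RYT = sum_i RY_i.  RYT > 1 indicates overyielding (facilitation); the
mixture-vs-expected ratio

    (Y_gra(mix) + Y_leg(mix)) / (Y_gra(mono) + Y_leg(mono))

summarises the whole-pot benefit of mixed cultivation.  Per-species RY and
the summed RYT are kept distinct throughout (some presentations label the
per-species ratios "RYT"; here RY always means the per-species ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TreatmentMeans",
    "OveryieldRow",
    "relative_yield",
    "overyield_table",
    "overyield_significance",
    "SignificanceVerdict",
]


@dataclass(frozen=True)
class TreatmentMeans:
    """Species-level yield means for one nutrient treatment (kpixels)."""

    treatment: str
    y_grass_mono: float
    y_grass_mix: float
    y_legume_mono: float
    y_legume_mix: float

    def __post_init__(self) -> None:
        for name in ("y_grass_mono", "y_grass_mix", "y_legume_mono", "y_legume_mix"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 for treatment {self.treatment}")


@dataclass(frozen=True)
class OveryieldRow:
    treatment: str
    ry_grass: float
    ry_legume: float
    ryt: float
    mono_ratio: float  # Y_gra : Y_leg (monocultures)
    mix_ratio: float  # Y_gra(mix) : Y_leg(mix)
    mix_vs_expected: float  # total mixture yield vs expected from monocultures
    pct_grass: float  # (ry_grass - 1) * 100
    pct_legume: float
    pct_total: float  # (mix_vs_expected - 1) * 100


def relative_yield(y_mix: float, y_mono: float) -> float:
    """RY = mixture yield / monoculture yield for one species."""
    if y_mono <= 0:
        raise ValueError(f"monoculture yield must be > 0, got {y_mono}")
    return y_mix / y_mono


def overyield_row(means: TreatmentMeans) -> OveryieldRow:
    ry_g = relative_yield(means.y_grass_mix, means.y_grass_mono)
    ry_l = relative_yield(means.y_legume_mix, means.y_legume_mono)
    mix_vs_exp = (means.y_grass_mix + means.y_legume_mix) / (
        means.y_grass_mono + means.y_legume_mono
    )
    return OveryieldRow(
        treatment=means.treatment,
        ry_grass=ry_g,
        ry_legume=ry_l,
        ryt=ry_g + ry_l,
        mono_ratio=means.y_grass_mono / means.y_legume_mono,
        mix_ratio=means.y_grass_mix / means.y_legume_mix,
        mix_vs_expected=mix_vs_exp,
        pct_grass=(ry_g - 1.0) * 100.0,
        pct_legume=(ry_l - 1.0) * 100.0,
        pct_total=(mix_vs_exp - 1.0) * 100.0,
    )


def overyield_table(means: list[TreatmentMeans] | dict[str, TreatmentMeans]) -> pd.DataFrame:
    """Full ratio suite, one row per nutrient treatment.

    Full precision is retained; presentation rounding (ratios to 2 decimals,
    percent changes to integers) is left to the caller or report writer.
    """
    if isinstance(means, dict):
        means = list(means.values())
    if not means:
        raise ValueError("no treatment means supplied")
    rows = [overyield_row(m) for m in means]
    return pd.DataFrame(
        {
            "treatment": [r.treatment for r in rows],
            "RY_grass": [r.ry_grass for r in rows],
            "RY_legume": [r.ry_legume for r in rows],
            "RYT": [r.ryt for r in rows],
            "Y_gra:Y_leg": [r.mono_ratio for r in rows],
            "Y_gra(Mix):Y_leg(Mix)": [r.mix_ratio for r in rows],
            "Y_mix:Y_expected": [r.mix_vs_expected for r in rows],
            "pct_grass": [r.pct_grass for r in rows],
            "pct_legume": [r.pct_legume for r in rows],
            "pct_total": [r.pct_total for r in rows],
        }
    )


@dataclass(frozen=True)
class SignificanceVerdict:
    species: str
    cultivation_significant: bool  # a reported cultivation term fired
    contrast_p: float  # mixture-vs-monoculture marginal-mean comparison
    direction: str  # "overyield", "underyield" or "none"
    significant_overyield: bool
    p_value: float  # smallest reported cultivation-term p


def overyield_significance(fit, alpha: float = 0.05) -> list[SignificanceVerdict]:
    """Per-species overyield verdicts from a fitted yield mixed model.

    A species is flagged as significantly overyielding when (i) a reported
    term containing cultivation passes the hierarchical Wald tests at
    ``alpha``, (ii) the mixture-vs-monoculture estimated-marginal-mean
    comparison (unadjusted t, the multiple-comparison step) is significant,
    and (iii) the mixture mean exceeds the monoculture mean.  The reverse
    ordering with the same test outcomes is a significant *under*yield.
    """
    from .mixed_model import wald_hierarchy, emm_contrast

    verdicts = []
    for species in ("grass", "legume"):
        tt = wald_hierarchy(fit, species, alpha=alpha)
        if not tt["term"].str.contains("C").any():
            raise ValueError(f"fit lacks a cultivation term for species {species!r}")
        cult_terms = tt[tt["term"].str.contains("C") & tt["reported"]]
        wald_sig = bool((cult_terms["p_value"] < alpha).any())
        p = float(cult_terms["p_value"].min()) if not cult_terms.empty else float("nan")
        con = emm_contrast(
            fit,
            ["species", "cultivation"],
            {"species": species, "cultivation": "mixture"},
            {"species": species, "cultivation": "mono"},
        )
        est = con["estimate"]
        direction = "overyield" if est > 0 else ("underyield" if est < 0 else "none")
        significant = wald_sig and con["p_value"] < alpha
        verdicts.append(
            SignificanceVerdict(
                species=species,
                cultivation_significant=wald_sig,
                contrast_p=con["p_value"],
                direction=direction,
                significant_overyield=significant and direction == "overyield",
                p_value=p,
            )
        )
    return verdicts
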