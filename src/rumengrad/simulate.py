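"""Synthetic feeding-trial generator.

Emulates the study design the analysis assumes: five diets on a
concentrate:roughage gradient (concentrate fractions 0.20-0.80), three
fistulated animals per diet, with

- diet nutrient profiles linear in the concentrate fraction (interpolated
  between a pure-roughage and a pure-concentrate endpoint, with the NDFn
  and NFC identities re-imposed so generated diets are internally
  consistent);
- fermentation responses following the trial's fitted gradient equations
  plus Gaussian noise: NH3-N = 2.0426*CP - 8.4155 (mg/dL), acetate
  proportion = 0.0012*NDF + 0.641, and pH = 7.2 - 0.02*starch (the pH
  coefficients are generator defaults chosen to keep pH inside the
  observed 6.0-7.0 band — no fitted pH equation is available to copy);
- compositional taxon tables whose expected proportions are the softmax
  of per-taxon log-linear responses log w_t = alpha_t + beta_t * x,
  sampled per animal as Dirichlet-multinomial counts (concentration
  theta, fixed sequencing depth);
- total-collection digestion records constructed from a configured true
  digestibility vector, so the digestibility pipeline has an exact truth
  to recover.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` child streams, so each generator is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .digestibility import ndfn_from_components, nfc_closure
from .trend import fit_linear
from .types import (
    AbundanceTable,
    DietSpec,
    FecalRecord,
    FermentationSample,
    IntakeRecord,
    NutrientProfile,
)

__all__ = [
    "GeneratorConfig",
    "default_config",
    "default_endpoints",
    "DEFAULT_TAXON_PARAMS",
    "gen_diets",
    "gen_fermentation",
    "gen_abundance",
    "gen_digestion_trial",
    "analytic_crossing",
    "expected_proportions",
]

# Per-taxon (alpha, beta) of log-weight = alpha + beta*x. Defaults emulate a
# buffalo rumen community: two dominant phyla whose expected proportions
# cross between concentrate fractions 0.6 and 0.9 (the core alternation),
# a rare exponentially-rising taxon, and minor taxa with mild trends.
DEFAULT_TAXON_PARAMS: dict[str, tuple[float, float]] = {
    "p_Bacteroidetes": (0.00, -0.95),
    "p_Firmicutes": (-1.30, 0.85),
    "p_Spirochaetes": (-6.20, 4.156),
    "p_Patescibacteria": (-4.40, -1.20),
    "p_Proteobacteria": (-5.00, 0.30),
    "p_Fibrobacteres": (-5.50, 0.50),
}

#: non-acetate VFA mix (shares of the non-acetate pool) used when
#: constructing per-acid concentrations; taken from the reference trial's
#: grand-mean acid profile
_NON_ACETATE_SHARES = {
    "propionic": 0.5604,
    "isobutyric": 0.0285,
    "butyric": 0.3268,
    "isovaleric": 0.0259,
    "pentanoic": 0.0435,
    "caproic": 0.0149,
}


@dataclass
class GeneratorConfig:
    """Design constants and noise levels of the synthetic trial."""

    fractions: tuple[float, ...] = (0.20, 0.35, 0.50, 0.65, 0.80)
    n_animals: int = 3
    seed: int = 0
    #: Gaussian sigma per response; zero means deterministic
    noise: dict[str, float] = field(
        default_factory=lambda: {
            "ph": 0.08,
            "nh3n": 1.5,
            "acetate_proportion": 0.015,
            "tvfa": 10.0,
            "digestibility": 0.02,  # relative sigma on excreted amounts
        }
    )
    endpoint_roughage: Optional[NutrientProfile] = None
    endpoint_concentrate: Optional[NutrientProfile] = None
    taxon_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_PARAMS)
    )
    theta: float = 200.0  # Dirichlet concentration (overdispersion)
    depth: int = 20000  # reads per sample
    ph_intercept: float = 7.2
    ph_slope_starch: float = -0.02
    tvfa_mean: float = 110.0  # mmol/L
    dm_intake_mean: float = 8.0  # kg DM/day
    body_weight_mean: float = 365.0  # kg

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing")
        if not all(0.0 <= f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        self.fractions = fr
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if any(s < 0 for s in self.noise.values()):
            raise ValueError("noise sigmas must be >= 0")
        if self.endpoint_roughage is None or self.endpoint_concentrate is None:
            rough, conc = default_endpoints()
            self.endpoint_roughage = self.endpoint_roughage or rough
            self.endpoint_concentrate = self.endpoint_concentrate or conc

    def stream(self, name: str) -> np.random.Generator:
        """A named, reproducible random stream derived from the master seed."""
        offsets = {"fermentation": 1, "abundance": 2, "digestion": 3}
        if name not in offsets:
            raise KeyError(f"unknown stream {name!r}")
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(offsets[name],))
        return np.random.default_rng(ss)


def default_endpoints() -> tuple[NutrientProfile, NutrientProfile]:
    """Pure-roughage (x=0) and pure-concentrate (x=1) nutrient profiles.

    Each nutrient of the bundled reference trial varies linearly along the
    gradient, so the endpoints are the x=0 and x=1 evaluations of OLS
    lines fitted to the five reference diets; NDFn and NFC are then
    recomputed from the identities so both endpoints are internally
    consistent.
    """
    x = list(reference.CONCENTRATE_FRACTIONS)
    ends: dict[str, list[float]] = {"rough": [], "conc": []}
    fields: dict[str, tuple[float, float]] = {}
    for nutrient in reference.DIET_NUTRIENTS.index:
        y = reference.DIET_NUTRIENTS.loc[nutrient].to_list()
        line = fit_linear(x, y)
        b0 = line.params["intercept"]
        b1 = line.params["slope"]
        fields[nutrient] = (b0, b0 + b1)
    def build(i: int) -> NutrientProfile:
        vals = {k: v[i] for k, v in fields.items()}
        vals["ndfn"] = ndfn_from_components(vals["ndf"], vals["ndicp"])
        vals["nfc"] = nfc_closure(vals["cp"], vals["ee"], vals["ash"], vals["ndfn"])
        return NutrientProfile(**vals)
    return build(0), build(1)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


def gen_diets(cfg: GeneratorConfig) -> list[DietSpec]:
    """One DietSpec per gradient level, nutrients linear in the fraction."""
    rough = cfg.endpoint_roughage.as_dict()
    conc = cfg.endpoint_concentrate.as_dict()
    shared = set(rough) & set(conc)
    diets = []
    for x in cfg.fractions:
        vals = {k: x * conc[k] + (1 - x) * rough[k] for k in shared}
        if "ndf" in vals and "ndicp" in vals:
            vals["ndfn"] = ndfn_from_components(vals["ndf"], vals["ndicp"])
        if all(k in vals for k in ("cp", "ee", "ash", "ndfn")):
            vals["nfc"] = nfc_closure(vals["cp"], vals["ee"], vals["ash"], vals["ndfn"])
        label = f"{round(x * 100):g}:{round((1 - x) * 100):g}"
        diets.append(
            DietSpec(group_label=label, concentrate_fraction=x,
                     profile=NutrientProfile(**vals))
        )
    return diets


def gen_fermentation(
    diets: Sequence[DietSpec], cfg: GeneratorConfig
) -> list[FermentationSample]:
    """Per animal x diet fermentation samples following the gradient equations.

    Acetate proportions falling outside (0, 1) under extreme noise are
    redrawn (truncated resampling); pH is clipped into (0, 14) the same
    way. TVFA is drawn around ``tvfa_mean`` and per-acid concentrations
    are constructed so acetic/TVFA equals the generated acetate proportion
    and the acids sum exactly to TVFA.
    """
    rng = cfg.stream("fermentation")
    s = cfg.noise
    k_nh, b_nh = reference.NH3N_CP_LINE
    k_ac, b_ac = reference.ACETATE_NDF_LINE
    out = []
    for diet in diets:
        p = diet.profile
        for a in range(cfg.n_animals):
            nh3n = k_nh * p.cp + b_nh + rng.normal(0, s["nh3n"]) if s["nh3n"] else k_nh * p.cp + b_nh
            ph = cfg.ph_intercept + cfg.ph_slope_starch * p.starch
            if s["ph"]:
                ph += rng.normal(0, s["ph"])
            acet = k_ac * p.ndf + b_ac
            if s["acetate_proportion"]:
                draw = acet + rng.normal(0, s["acetate_proportion"])
                while not 0.0 < draw < 1.0:
                    draw = acet + rng.normal(0, s["acetate_proportion"])
                acet = draw
            tvfa = cfg.tvfa_mean
            if s["tvfa"]:
                draw = tvfa + rng.normal(0, s["tvfa"])
                while draw <= 0:
                    draw = tvfa + rng.normal(0, s["tvfa"])
                tvfa = draw
            vfa = {"acetic": acet * tvfa}
            rest = (1.0 - acet) * tvfa
            for acid, share in _NON_ACETATE_SHARES.items():
                vfa[acid] = rest * share
            # close the tiny share-rounding gap on the largest non-acetate acid
            gap = tvfa - sum(vfa.values())
            vfa["propionic"] += gap
            out.append(
                FermentationSample(
                    animal_id=f"A{a + 1}",
                    group_label=diet.group_label,
                    ph=float(np.clip(ph, 1e-6, 14 - 1e-6)),
                    nh3n=float(nh3n),
                    vfa={k: float(v) for k, v in vfa.items()},
                )
            )
    return out


def expected_proportions(
    cfg: GeneratorConfig, x: float | np.ndarray
) -> pd.DataFrame | pd.Series:
    """Expected taxon proportions at concentrate fraction(s) x: softmax(alpha + beta*x)."""
    taxa = list(cfg.taxon_params)
    a = np.array([cfg.taxon_params[t][0] for t in taxa])
    b = np.array([cfg.taxon_params[t][1] for t in taxa])
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    w = np.exp(a[:, None] + b[:, None] * xs[None, :])
    p = w / w.sum(axis=0)
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return pd.Series(p[:, 0], index=taxa)
    return pd.DataFrame(p, index=taxa, columns=list(xs))


def analytic_crossing(cfg: GeneratorConfig, taxon_a: str, taxon_b: str) -> float:
    """Exact gradient position where two taxa's expected proportions are equal.

    The softmax normaliser cancels in the log-difference, so the crossing
    solves alpha_a + beta_a*x = alpha_b + beta_b*x in closed form.
    """
    a_a, b_a = cfg.taxon_params[taxon_a]
    a_b, b_b = cfg.taxon_params[taxon_b]
    if b_a == b_b:
        raise ValueError("equal betas: expected curves never cross")
    return (a_b - a_a) / (b_a - b_b)


def gen_abundance(
    diets: Sequence[DietSpec], cfg: GeneratorConfig, exact: bool = False
) -> AbundanceTable:
    """Taxon-by-sample counts from the Dirichlet-multinomial community model.

    With ``exact=True`` no sampling happens: the returned table holds the
    expected proportions themselves, one column per gradient level
    (proportions mode) — the zero-noise limit used for parameter-recovery
    checks.
    """
    if len(cfg.taxon_params) < 2:
        raise ValueError("need >= 2 taxa to form a community")
    taxa = list(cfg.taxon_params)
    if exact:
        cols, meta_rows = {}, []
        for diet in diets:
            p = expected_proportions(cfg, diet.concentrate_fraction)
            sid = f"G{diet.group_label}"
            cols[sid] = p
            meta_rows.append((sid, diet.group_label, diet.concentrate_fraction))
        values = pd.DataFrame(cols)
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "group_label", "concentrate_fraction"]
        ).set_index("sample_id")
        return AbundanceTable(values=values, metadata=meta, mode="proportions")

    rng = cfg.stream("abundance")
    cols, meta_rows = {}, []
    for diet in diets:
        p = expected_proportions(cfg, diet.concentrate_fraction).to_numpy()
        for a in range(cfg.n_animals):
            probs = rng.dirichlet(cfg.theta * p)
            counts = rng.multinomial(cfg.depth, probs)
            sid = f"A{a + 1}.{diet.group_label}"
            cols[sid] = counts
            meta_rows.append((sid, diet.group_label, diet.concentrate_fraction))
    values = pd.DataFrame(cols, index=taxa)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "group_label", "concentrate_fraction"]
    ).set_index("sample_id")
    return AbundanceTable(values=values, metadata=meta, mode="counts")


def gen_digestion_trial(
    diets: Sequence[DietSpec],
    cfg: GeneratorConfig,
    true_digestibility: Mapping[str, float],
    sigma: Optional[float] = None,
) -> tuple[list[IntakeRecord], list[FecalRecord]]:
    """Intake and fecal records realising a configured true digestibility.

    Fecal nutrient amounts are intake_amount * (1 - d/100) * (1 + eps)
    with eps ~ N(0, sigma) (sigma defaults to ``cfg.noise['digestibility']``,
    relative scale). With sigma = 0 the digestibility pipeline recovers
    ``true_digestibility`` exactly. ``true_digestibility`` must contain a
    ``dm`` entry (total fecal DM is built from it); other nutrients are
    optional and only those present end up in the fecal profiles.
    """
    for k, d in true_digestibility.items():
        if not 0.0 <= d <= 100.0:
            raise ValueError(f"true digestibility of {k} outside [0, 100]: {d}")
    if "dm" not in true_digestibility:
        raise ValueError("true_digestibility must include 'dm'")
    if {"ndf", "ndicp", "ndfn"} <= set(true_digestibility):
        raise ValueError(
            "over-determined truth: ndfn excretion is fixed by ndf and ndicp "
            "through the NDFn identity; configure at most two of the three"
        )
    if sigma is None:
        sigma = cfg.noise.get("digestibility", 0.0)
    rng = cfg.stream("digestion")
    intakes, feces = [], []
    for period, diet in enumerate(diets, start=1):
        for a in range(cfg.n_animals):
            animal = f"A{a + 1}"
            dm_intake = cfg.dm_intake_mean
            eps = rng.normal(0, sigma) if sigma else 0.0
            fecal_dm = dm_intake * (1 - true_digestibility["dm"] / 100.0) * (1 + eps)
            fecal_pct: dict[str, float] = {}
            profile = diet.profile.as_dict()
            for nutrient, d in true_digestibility.items():
                if nutrient == "dm" or nutrient not in profile:
                    continue
                intake_amt = dm_intake * profile[nutrient] / 100.0
                eps_n = rng.normal(0, sigma) if sigma else 0.0
                excr_amt = intake_amt * (1 - d / 100.0) * (1 + eps_n)
                if fecal_dm > 0:
                    fecal_pct[nutrient] = min(100.0 * excr_amt / fecal_dm, 100.0)
            intakes.append(
                IntakeRecord(
                    animal_id=animal,
                    period=period,
                    dm_intake=dm_intake,
                    body_weight=cfg.body_weight_mean,
                    diet=diet,
                )
            )
            feces.append(
                FecalRecord(
                    animal_id=animal,
                    period=period,
                    fecal_dm=float(fecal_dm),
                    nutrient_conc=NutrientProfile(**fecal_pct),
                )
            )
    return intakes, feces
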