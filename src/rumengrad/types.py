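"""Domain types for the concentrate:roughage gradient analysis.

Units follow feed-science convention: nutrient concentrations are % of dry
matter (DM), gross energy is cal/g, intake masses are kg DM/day, ammonia
nitrogen (NH3-N) is mg/dL, and volatile fatty acids (VFA) are mmol/L.
The gradient variable throughout is the concentrate fraction of the diet,
a dimensionless number in [0, 1] (a "65:35" concentrate:roughage diet has
concentrate fraction 0.65).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "NutrientProfile",
    "DietSpec",
    "IntakeRecord",
    "FecalRecord",
    "FermentationSample",
    "AbundanceTable",
    "StandardCurve",
    "TrendModel",
    "DigestibilityResult",
    "DiversityResult",
    "CrossoverPoint",
    "SaraAssessment",
    "VFA_ACIDS",
    "parse_ratio_label",
    "taxon_rank",
]

#: canonical acid order for VFA maps
VFA_ACIDS = (
    "acetic",
    "propionic",
    "isobutyric",
    "butyric",
    "isovaleric",
    "pentanoic",
    "caproic",
)

#: rank prefixes conventionally used in 16S taxonomy strings
_RANK_PREFIXES = {
    "p_": "phylum",
    "c_": "class",
    "o_": "order",
    "f_": "family",
    "g_": "genus",
}


def taxon_rank(taxon: str) -> Optional[str]:
    """Rank of a prefixed taxon identifier (``p_Bacteroidetes`` -> ``phylum``).

    Returns None when the identifier carries no recognised prefix.
    For pipe-joined lineages (``o_Bacteroidales|f_F082|g_``) the rank of the
    last non-empty component is used.
    """
    for part in reversed(taxon.split("|")):
        for prefix, rank in _RANK_PREFIXES.items():
            if part.startswith(prefix) and len(part) > len(prefix):
                return rank
    return None


def taxon_at_rank(taxon: str, rank: str) -> Optional[str]:
    """The component of a (possibly pipe-joined) identifier at the given rank.

    ``taxon_at_rank("p_Bacteroidetes|g_Prevotella 1", "phylum")`` returns
    ``"p_Bacteroidetes"``. Returns None when no component carries the
    requested rank's prefix.
    """
    prefixes = [p for p, r in _RANK_PREFIXES.items() if r == rank]
    if not prefixes:
        raise ValueError(f"unknown rank {rank!r}")
    for part in taxon.split("|"):
        for prefix in prefixes:
            if part.startswith(prefix) and len(part) > len(prefix):
                return part
    return None


def parse_ratio_label(label: str) -> float:
    """Concentrate fraction from a ``"c:r"`` ratio label (``"20:80"`` -> 0.20).

    Raises ValueError when the label is not two numbers summing to 100
    (or to 1 when given as fractions, e.g. ``"0.2:0.8"``).
    """
    parts = label.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"cannot parse group label {label!r} as 'c:r'")
    try:
        c, r = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ValueError(f"cannot parse group label {label!r} as 'c:r'") from exc
    total = c + r
    if math.isclose(total, 100.0, rel_tol=1e-6):
        return c / 100.0
    if math.isclose(total, 1.0, rel_tol=1e-6):
        return c
    raise ValueError(f"group label {label!r}: parts must sum to 100 (or 1)")


_PCT_FIELDS = (
    "dm", "om", "cp", "ee", "ash", "ca", "p", "ndf", "adf", "adl",
    "ndicp", "adicp", "nfc", "ndfn", "starch",
)


@dataclass
class NutrientProfile:
    """Nutrient concentrations of a feed or of feces, % of dry matter.

    All concentration fields are optional (None means not measured, never
    zero). ``ge`` is gross energy in cal/g DM. Validation enforces the
    [0, 100] range for percentages and, when ndf/ndicp/ndfn are all present,
    the protein-corrected NDF identity ndfn = ndf - ndicp within a rounding
    tolerance.
    """

    dm: Optional[float] = None
    om: Optional[float] = None
    cp: Optional[float] = None
    ee: Optional[float] = None
    ash: Optional[float] = None
    ca: Optional[float] = None
    p: Optional[float] = None
    ndf: Optional[float] = None
    adf: Optional[float] = None
    adl: Optional[float] = None
    ndicp: Optional[float] = None
    adicp: Optional[float] = None
    nfc: Optional[float] = None
    ndfn: Optional[float] = None
    starch: Optional[float] = None
    ge: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] % of DM")
        if self.ge is not None and self.ge < 0:
            raise ValueError(f"ge={self.ge} must be >= 0")
        if self.ndf is not None and self.ndicp is not None and self.ndfn is not None:
            if abs(self.ndfn - (self.ndf - self.ndicp)) > 0.05:
                raise ValueError(
                    f"ndfn={self.ndfn} inconsistent with ndf-ndicp="
                    f"{self.ndf - self.ndicp:.4f}"
                )

    def as_dict(self, drop_none: bool = True) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            out = {k: v for k, v in out.items() if v is not None}
        return out


@dataclass
class DietSpec:
    """One experimental diet: its label, concentrate fraction and profile."""

    group_label: str
    concentrate_fraction: float
    profile: NutrientProfile

    def __post_init__(self) -> None:
        if not (0.0 <= self.concentrate_fraction <= 1.0):
            raise ValueError(
                f"concentrate_fraction={self.concentrate_fraction} outside [0, 1]"
            )


@dataclass
class IntakeRecord:
    """Daily dry-matter intake of one animal in one period."""

    animal_id: str
    period: int
    dm_intake: float  # kg DM/day
    body_weight: float  # kg
    diet: DietSpec

    def __post_init__(self) -> None:
        if self.dm_intake < 0:
            raise ValueError("dm_intake must be >= 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


@dataclass
class FecalRecord:
    """Daily fecal dry-matter output and its nutrient profile."""

    animal_id: str
    period: int
    fecal_dm: float  # kg DM/day
    nutrient_conc: NutrientProfile

    def __post_init__(self) -> None:
        if self.fecal_dm < 0:
            raise ValueError("fecal_dm must be >= 0")


@dataclass
class FermentationSample:
    """Rumen-fluid fermentation measurements for one animal.

    ``vfa`` maps acid name -> mmol/L; ``tvfa`` is their molar sum and
    ``acetate_proportion`` is acetic/tvfa, both validated within a relative
    tolerance generous enough for tabulated (rounded) inputs.
    """

    animal_id: str
    group_label: str
    ph: float
    nh3n: float
    vfa: dict[str, float] = field(default_factory=dict)
    tvfa: Optional[float] = None
    acetate_proportion: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ph < 14.0):
            raise ValueError(f"ph={self.ph} outside (0, 14)")
        if self.vfa:
            total = float(sum(self.vfa.values()))
            if self.tvfa is None:
                self.tvfa = total
            elif not math.isclose(self.tvfa, total, rel_tol=5e-3, abs_tol=0.5):
                raise ValueError(
                    f"tvfa={self.tvfa} != sum of acids {total:.4f}"
                )
            if "acetic" in self.vfa and self.tvfa > 0:
                prop = self.vfa["acetic"] / self.tvfa
                if self.acetate_proportion is None:
                    self.acetate_proportion = prop
                elif not math.isclose(
                    self.acetate_proportion, prop, rel_tol=2e-2, abs_tol=5e-3
                ):
                    raise ValueError(
                        f"acetate_proportion={self.acetate_proportion} "
                        f"inconsistent with acetic/tvfa={prop:.4f}"
                    )


@dataclass
class StandardCurve:
    """Linear colorimetric standard curve: absorbance = slope*conc + intercept."""

    slope: float
    intercept: float
    r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be nonzero")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 outside [0, 1]")


@dataclass
class AbundanceTable:
    """Taxon-by-sample abundance matrix with per-sample gradient metadata.

    ``values`` is a DataFrame with taxa as the index and samples as columns;
    ``metadata`` is indexed by sample id with at least ``group_label`` and
    ``concentrate_fraction`` columns. ``mode`` distinguishes raw counts from
    relative abundances (proportions; each column sums to 1).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    mode: Literal["counts", "proportions"]

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"unknown mode {self.mode!r}")
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            ti, si = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {self.values.index[ti]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in ("group_label", "concentrate_fraction"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if self.mode == "proportions":
            sums = v.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.values.columns[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(
                    f"proportions-mode column {bad!r} does not sum to 1"
                )

    # ---- convenience accessors -------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def fractions(self) -> pd.Series:
        """Concentrate fraction per sample, aligned to the column order."""
        return self.metadata.loc[self.samples, "concentrate_fraction"].astype(float)

    def group_labels(self) -> pd.Series:
        return self.metadata.loc[self.samples, "group_label"]


@dataclass
class TrendModel:
    """A fitted response curve of one variable along the gradient.

    families and parameterisations:
      - ``linear``:      y = slope*x + intercept
      - ``quadratic``:   y = b2*x^2 + b1*x + b0       (params b2, b1, b0)
      - ``exponential``: y = a * exp(k*x)             (params a, k)

    ``r2`` is the coefficient of determination on the family's fitting
    scale (log scale for the exponential family, which is fitted by OLS on
    ln y); ``r2_original`` is always 1 - SSres/SStot on the original y
    scale and is the value used when comparing families.
    """

    family: Literal["linear", "quadratic", "exponential"]
    params: dict[str, float]
    r2: float
    x_range: tuple[float, float]
    n: int
    r2_original: Optional[float] = None

    _N_PARAMS = {"linear": 2, "quadratic": 3, "exponential": 2}

    def __post_init__(self) -> None:
        if self.family not in self._N_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < self._N_PARAMS[self.family]:
            raise ValueError(
                f"n={self.n} below number of coefficients for {self.family}"
            )
        if not (-1e-9 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError(f"r2={self.r2} outside [0, 1]")
        lo, hi = self.x_range
        if not lo < hi:
            raise ValueError(f"degenerate x_range {self.x_range}")

    @property
    def n_params(self) -> int:
        return self._N_PARAMS[self.family]

    def __call__(self, x):
        from .trend import predict  # local import to avoid a cycle

        return predict(self, x)


@dataclass
class DigestibilityResult:
    """Per-nutrient apparent digestibility (%) for one animal-period."""

    animal_id: str
    period: int
    digestibility: dict[str, float]  # nutrient -> % (may be negative)
    nutrient_intake: dict[str, float]  # kg/day (cal/day for ge)
    nutrient_excretion: dict[str, float]

    def __post_init__(self) -> None:
        for k, d in self.digestibility.items():
            if d > 100.0 + 1e-9:
                raise ValueError(f"digestibility of {k} above 100%: {d}")


@dataclass
class DiversityResult:
    """Alpha diversity of one sample: Shannon index (natural log) and richness."""

    sample_id: str
    shannon: float
    richness: int

    def __post_init__(self) -> None:
        if self.shannon < -1e-12:
            raise ValueError("shannon must be >= 0")
        if self.richness >= 1 and self.shannon > math.log(self.richness) + 1e-9:
            raise ValueError("shannon exceeds ln(richness)")


CrossoverCase = Literal["opposite_direction", "same_direction", "curve_involved"]


@dataclass
class CrossoverPoint:
    """A gradient position where two taxa's fitted trend curves intersect.

    ``x_star`` is the concentrate fraction of the intersection (possibly in
    the slightly extended search range), ``y_star`` the shared abundance
    there, ``in_range`` whether x_star lies within the fitted data span,
    and ``case`` the qualitative classification: two lines of opposite
    slope sign, two lines of same-signed but unequal slope, or any pair
    involving a curved (non-linear) trend.
    """

    taxon_a: str
    taxon_b: str
    x_star: float
    y_star: float
    in_range: bool
    case: CrossoverCase
    model_a: TrendModel
    model_b: TrendModel


@dataclass
class SaraAssessment:
    """Rumen-health assessment combining chemistry thresholds and alternation points.

    pH status bands: normal >= 6.0, caution [5.6, 6.0), subacute [5.0, 5.6),
    acute < 5.0. NH3-N status: deficient < 5 mg/dL, optimal 5-27.5,
    excess > 27.5. ``alternation_flags`` lists trend-crossovers at or below
    the evaluated concentrate fraction.
    """

    subject_id: str
    ph_status: Optional[Literal["normal", "caution", "subacute", "acute"]]
    nh3n_status: Optional[Literal["deficient", "optimal", "excess"]]
    alternation_flags: list[CrossoverPoint]
    narrative: str
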