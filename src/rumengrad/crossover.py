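"""Trend-line crossover ("alternation point") detection and the SARA report.

As the concentrate fraction of a ruminant diet rises, the fitted abundance
trends of different rumen taxa cross each other: the point where a
declining taxon's curve meets a rising one marks a reorganisation of the
community. The crossing of the two core phyla (Bacteroidetes falling,
Firmicutes rising) sits near the gradient position where rumen chemistry
deteriorates (lowest pH, highest ammonia), which motivates using these
alternation points as an early-warning statistic for subacute ruminal
acidosis (SARA) alongside the classical pH and NH3-N thresholds.

Three qualitative crossing cases are distinguished:

- ``opposite_direction`` — two lines, slopes of strictly opposite sign
  (one taxon replaces the other);
- ``same_direction``    — two lines moving the same way but at different
  rates, meeting because of the slope difference;
- ``curve_involved``    — at least one trend is non-linear (parabola or
  exponential) and intersects the other curve.

Linear-linear pairs are solved in closed form; any pair involving a
non-linear family is solved by a sign-change scan over 1000 equal
subintervals followed by root refinement to |dx| < 1e-10.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .abundance import group_mean_table
from .types import (
    AbundanceTable,
    CrossoverPoint,
    FermentationSample,
    SaraAssessment,
    TrendModel,
)
from .trend import fit_exponential, fit_linear, fit_quadratic, predict, select_family

__all__ = [
    "fit_taxon_trends",
    "find_crossover",
    "classify_case",
    "alternation_report",
    "sara_assess",
    "PH_ACUTE",
    "PH_SUBACUTE",
    "PH_CAUTION",
    "NH3N_LOW",
    "NH3N_HIGH",
]

logger = logging.getLogger(__name__)

# rumen-health thresholds
PH_ACUTE = 5.0      # pH below this: acute ruminal acidosis
PH_SUBACUTE = 5.6   # pH below this: subacute ruminal acidosis (SARA)
PH_CAUTION = 6.0    # pH below this impairs fibrolytic microbes
NH3N_LOW = 5.0      # mg/dL, lower bound of the optimal NH3-N band
NH3N_HIGH = 27.5    # mg/dL, upper bound of the optimal NH3-N band

#: extension beyond the data span when searching for crossings; crossings
#: out there are reported but flagged not-in-range
RANGE_PAD = 0.05


def fit_taxon_trends(
    table: AbundanceTable,
    rank: Optional[str] = None,
    family: str = "auto",
    min_prevalence: int = 3,
    use_group_means: bool = True,
) -> dict[str, TrendModel]:
    """Fit one trend model per taxon against the concentrate fraction.

    By default each taxon's per-group mean proportion is regressed on the
    group's concentrate fraction (group-level fitting, matching how
    five-point gradient equations are usually derived); set
    ``use_group_means=False`` to fit on every sample instead. Taxa present
    (non-zero) in fewer than ``min_prevalence`` samples are skipped.
    ``family`` is one of ``linear``, ``quadratic``, ``exponential`` or
    ``auto`` (best original-scale r2). With a fixed ``exponential`` family
    taxa containing zeros are skipped with a log message rather than
    crashing the whole table.
    """
    if table.mode != "proportions":
        raise ValueError("fit_taxon_trends requires a proportions-mode table")
    work = table
    if rank is not None:
        from .abundance import aggregate_rank

        work = aggregate_rank(work, rank)
    fracs = work.fractions()
    if fracs.nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct gradient levels, got {fracs.nunique()}"
        )
    if use_group_means:
        means = group_mean_table(work)
        x = np.array([means.attrs["fractions"][g] for g in means.columns])
        data = means
    else:
        x = fracs.to_numpy(dtype=float)
        data = work.values

    fitters = {
        "linear": fit_linear,
        "quadratic": fit_quadratic,
        "exponential": fit_exponential,
    }
    trends: dict[str, TrendModel] = {}
    for taxon in data.index:
        y_all = work.values.loc[taxon] if taxon in work.values.index else data.loc[taxon]
        if int((np.asarray(y_all, dtype=float) > 0).sum()) < min_prevalence:
            logger.info("taxon %s below prevalence filter; skipped", taxon)
            continue
        y = data.loc[taxon].to_numpy(dtype=float)
        try:
            if family == "auto":
                trends[taxon] = select_family(x, y)
            else:
                trends[taxon] = fitters[family](x, y)
        except KeyError:
            raise ValueError(f"unknown family {family!r}") from None
        except ValueError as exc:
            logger.info("taxon %s not fitted (%s); skipped", taxon, exc)
    return trends


def _models_identical(a: TrendModel, b: TrendModel, tol: float = 1e-12) -> bool:
    if a.family != b.family:
        return False
    return all(
        abs(a.params[k] - b.params[k]) <= tol * max(1.0, abs(a.params[k]))
        for k in a.params
    )


def find_crossover(
    model_a: TrendModel,
    model_b: TrendModel,
    x_range: tuple[float, float],
    data_range: Optional[tuple[float, float]] = None,
    taxon_a: str = "a",
    taxon_b: str = "b",
) -> list[CrossoverPoint]:
    """All intersections of two fitted trend curves within ``x_range``.

    Linear pairs use the closed form x* = (b0_b - b0_a)/(b1_a - b1_b);
    parallel distinct lines give an empty list and coincident curves are a
    hard error (infinitely many intersections). Pairs involving a
    non-linear family are scanned for sign changes of the difference
    function on 1000 equal subintervals, each bracketed root then refined
    by bisection (Brent) to |dx| < 1e-10. Each returned point is flagged
    ``in_range`` relative to ``data_range`` (defaults to ``x_range``).
    """
    x_lo, x_hi = float(x_range[0]), float(x_range[1])
    if not x_lo < x_hi:
        raise ValueError(f"invalid range {x_range}")
    if data_range is None:
        data_range = (x_lo, x_hi)
    if _models_identical(model_a, model_b):
        raise ValueError("coincident models: infinite intersection set")

    def diff(x: float) -> float:
        return predict(model_a, x) - predict(model_b, x)

    roots: list[float] = []
    if model_a.family == "linear" and model_b.family == "linear":
        s_a, i_a = model_a.params["slope"], model_a.params["intercept"]
        s_b, i_b = model_b.params["slope"], model_b.params["intercept"]
        if s_a == s_b:
            return []  # parallel, distinct (coincident handled above)
        x_star = (i_b - i_a) / (s_a - s_b)
        if x_lo <= x_star <= x_hi:
            roots.append(x_star)
    else:
        grid = np.linspace(x_lo, x_hi, 1001)
        vals = np.array([diff(g) for g in grid])
        for g, v in zip(grid, vals):
            if v == 0.0:
                roots.append(float(g))
        sign = np.sign(vals)
        for i in range(len(grid) - 1):
            if sign[i] == 0 or sign[i + 1] == 0:
                continue
            if sign[i] != sign[i + 1]:
                r = optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-12)
                roots.append(float(r))
        # de-duplicate roots found twice at grid nodes
        roots = sorted(roots)
        dedup: list[float] = []
        for r in roots:
            if not dedup or abs(r - dedup[-1]) > 1e-9:
                dedup.append(r)
        roots = dedup

    points = []
    for r in sorted(roots):
        y_a = predict(model_a, r)
        y_b = predict(model_b, r)
        assert abs(y_a - y_b) < 1e-9, "solver failed the model-agreement invariant"
        points.append(
            CrossoverPoint(
                taxon_a=taxon_a,
                taxon_b=taxon_b,
                x_star=float(r),
                y_star=float(0.5 * (y_a + y_b)),
                in_range=bool(data_range[0] <= r <= data_range[1]),
                case=classify_case(model_a, model_b, r),
                model_a=model_a,
                model_b=model_b,
            )
        )
    return points


def classify_case(model_a: TrendModel, model_b: TrendModel, x_star: float) -> str:
    """Qualitative class of a crossing: see module docstring for the three cases."""
    if model_a.family != "linear" or model_b.family != "linear":
        return "curve_involved"
    s_a = model_a.params["slope"]
    s_b = model_b.params["slope"]
    if s_a * s_b < 0:
        return "opposite_direction"
    return "same_direction"


def _default_core_pair(
    trends: Mapping[str, TrendModel], x_lo: float
) -> Optional[tuple[str, str]]:
    """The two taxa most abundant (by model prediction) at the low end of the gradient."""
    if len(trends) < 2:
        return None
    ranked = sorted(trends, key=lambda t: predict(trends[t], x_lo), reverse=True)
    return ranked[0], ranked[1]


def alternation_report(
    trends: Mapping[str, TrendModel],
    x_range: tuple[float, float],
    focus_pairs: Optional[Sequence[tuple[str, str]]] = None,
    core_pair: Optional[tuple[str, str]] = None,
) -> dict:
    """All pairwise trend crossings, sorted by gradient position.

    The search range is extended by ``RANGE_PAD`` on each side of
    ``x_range`` (crossings often sit near the data edge) but points are
    flagged ``in_range`` only within the data span. The warning point is
    the smallest in-range crossing of the designated core pair (default:
    the two taxa dominating the low-gradient end, i.e. the core phyla).

    Returns a dict with keys ``crossovers`` (list of CrossoverPoint),
    ``warning_point`` (float or None), ``core_pair`` and ``narrative``.
    """
    if len(trends) < 2:
        raise ValueError("need >= 2 fitted taxa")
    x_lo, x_hi = float(x_range[0]), float(x_range[1])
    search = (x_lo - RANGE_PAD, x_hi + RANGE_PAD)
    names = list(trends)
    if focus_pairs is None:
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    else:
        pairs = [tuple(p) for p in focus_pairs]
        for a, b in pairs:
            for t in (a, b):
                if t not in trends:
                    raise KeyError(f"focus pair taxon {t!r} has no fitted trend")

    crossings: list[CrossoverPoint] = []
    for a, b in pairs:
        try:
            pts = find_crossover(
                trends[a], trends[b], search, data_range=(x_lo, x_hi),
                taxon_a=a, taxon_b=b,
            )
        except ValueError:
            logger.info("pair (%s, %s): coincident models, skipped", a, b)
            continue
        crossings.extend(pts)
    crossings.sort(key=lambda c: c.x_star)
    for c in crossings:
        if not c.in_range:
            logger.warning(
                "crossing of %s/%s at x=%.4f lies outside the data span",
                c.taxon_a, c.taxon_b, c.x_star,
            )

    if core_pair is None:
        core_pair = _default_core_pair(trends, x_lo)
    warning_point = None
    if core_pair is not None:
        core_set = frozenset(core_pair)
        core_in_range = [
            c.x_star
            for c in crossings
            if frozenset((c.taxon_a, c.taxon_b)) == core_set and c.in_range
        ]
        if core_in_range:
            warning_point = min(core_in_range)

    in_range = [c for c in crossings if c.in_range]
    if not in_range:
        narrative = "none: no trend-line alternation inside the data range"
    else:
        parts = [
            f"{c.taxon_a}/{c.taxon_b} alternate at concentrate fraction "
            f"{c.x_star:.4f} ({c.case})"
            for c in in_range
        ]
        narrative = "; ".join(parts)
        if warning_point is not None:
            narrative += (
                f". Core-pair warning point at concentrate fraction {warning_point:.4f}"
            )
    return {
        "crossovers": crossings,
        "warning_point": warning_point,
        "core_pair": core_pair,
        "narrative": narrative,
    }


def sara_assess(
    ferm: Optional[FermentationSample],
    report: Optional[dict] = None,
    x_eval: Optional[float] = None,
    ph: Optional[float] = None,
    nh3n: Optional[float] = None,
    subject_id: str = "",
) -> SaraAssessment:
    """Combine chemistry thresholds and alternation points into one assessment.

    pH and NH3-N may come from a FermentationSample or be given directly;
    at least one of the two measurements is required. ``report`` is an
    :func:`alternation_report` output and ``x_eval`` the concentrate
    fraction of the diet being assessed: every crossover at or below
    x_eval is flagged (the community has already passed its alternation
    point at that inclusion level).
    """
    if ferm is not None:
        ph = ferm.ph if ph is None else ph
        nh3n = ferm.nh3n if nh3n is None else nh3n
        subject_id = subject_id or f"{ferm.animal_id}/{ferm.group_label}"
    if ph is None and nh3n is None:
        raise ValueError("need at least one of pH or NH3-N")

    notes: list[str] = []
    ph_status = None
    if ph is not None:
        if ph < PH_ACUTE:
            ph_status = "acute"
            notes.append(f"pH {ph:.2f} < {PH_ACUTE}: acute ruminal acidosis")
        elif ph < PH_SUBACUTE:
            ph_status = "subacute"
            notes.append(f"pH {ph:.2f} < {PH_SUBACUTE}: subacute ruminal acidosis")
        elif ph < PH_CAUTION:
            ph_status = "caution"
            notes.append(
                f"pH {ph:.2f} < {PH_CAUTION}: fibrolytic activity impaired"
            )
        else:
            ph_status = "normal"
    nh3n_status = None
    if nh3n is not None:
        if nh3n < NH3N_LOW:
            nh3n_status = "deficient"
            notes.append(
                f"NH3-N {nh3n:.1f} mg/dL below the optimal band "
                f"[{NH3N_LOW}, {NH3N_HIGH}]"
            )
        elif nh3n > NH3N_HIGH:
            nh3n_status = "excess"
            notes.append(
                f"NH3-N {nh3n:.1f} mg/dL above the optimal band "
                f"[{NH3N_LOW}, {NH3N_HIGH}]"
            )
        else:
            nh3n_status = "optimal"

    flags: list[CrossoverPoint] = []
    if report is not None and x_eval is not None:
        flags = [c for c in report["crossovers"] if c.x_star <= x_eval]
        for c in flags:
            notes.append(
                f"alternation point {c.taxon_a}/{c.taxon_b} at "
                f"{c.x_star:.4f} <= evaluated fraction {x_eval:.2f}"
            )
    if not notes:
        notes.append("all indicators within normal bands")
    return SaraAssessment(
        subject_id=subject_id,
        ph_status=ph_status,
        nh3n_status=nh3n_status,
        alternation_flags=flags,
        narrative="; ".join(notes),
    )
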