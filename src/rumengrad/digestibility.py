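"""Total-collection apparent digestibility and feed-composition identities.

Apparent digestibility of a nutrient over a total-collection period is

    100 * (nutrient intake - fecal nutrient excretion) / nutrient intake   [%]

with both amounts on a dry-matter basis (DM mass * nutrient %DM / 100).
Negative values are possible with real collection data (endogenous
excretion, measurement error) and are reported as-is with a warning, never
clipped.

Also here: the protein-corrected fiber identity NDFn = NDF - NDICP, the
non-fibrous-carbohydrate closure NFC = 100 - CP - EE - Ash - NDFn, and
intake scaling by metabolic body weight (g DM per kg BW^0.75).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import DietSpec, DigestibilityResult, FecalRecord, IntakeRecord

__all__ = [
    "apparent_digestibility",
    "trial_digestibility",
    "ndfn_from_components",
    "nfc_closure",
    "dmi_per_metabolic_weight",
    "mean_digestibility",
]

logger = logging.getLogger(__name__)


def apparent_digestibility(intake: float, excretion: float) -> float:
    """Apparent digestibility (%) from nutrient intake and fecal excretion.

    Both arguments share any amount/day unit. Raises for non-positive
    intake (the quantity is undefined) or negative excretion. Values above
    intake give a negative digestibility, reported with a warning.
    """
    if intake <= 0:
        raise ValueError(f"intake must be > 0, got {intake}")
    if excretion < 0:
        raise ValueError(f"excretion must be >= 0, got {excretion}")
    d = 100.0 * (intake - excretion) / intake
    if d < 0:
        logger.warning(
            "negative apparent digestibility (%.2f%%): excretion %.4g exceeds intake %.4g",
            d, excretion, intake,
        )
    return d


def ndfn_from_components(ndf: float, ndicp: float) -> float:
    """Protein-corrected NDF: NDF minus neutral-detergent-insoluble CP (% DM)."""
    if ndicp < 0 or ndf < 0:
        raise ValueError("ndf and ndicp must be >= 0")
    if ndicp > ndf:
        raise ValueError(f"ndicp={ndicp} exceeds ndf={ndf}")
    return ndf - ndicp


def nfc_closure(cp: float, ee: float, ash: float, ndfn: float) -> float:
    """Non-fibrous carbohydrate by difference: 100 - CP - EE - Ash - NDFn (% DM)."""
    nfc = 100.0 - cp - ee - ash - ndfn
    if nfc < 0:
        raise ValueError(
            f"components sum to {100.0 - nfc:.2f} > 100; composition inconsistent"
        )
    return nfc


def dmi_per_metabolic_weight(dm_intake: float, body_weight: float) -> float:
    """Dry-matter intake scaled to metabolic body weight: g DM per kg BW^0.75."""
    if body_weight <= 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    if dm_intake < 0:
        raise ValueError(f"dm_intake must be >= 0, got {dm_intake}")
    return 1000.0 * dm_intake / body_weight**0.75


def trial_digestibility(
    intakes: Iterable[IntakeRecord],
    feces: Iterable[FecalRecord],
    diet: DietSpec | None = None,
) -> list[DigestibilityResult]:
    """Per-animal-period apparent digestibility from matched intake and fecal records.

    Records are matched on (animal_id, period); an unmatched key on either
    side is a hard error. For every nutrient present in both the diet
    profile and the fecal profile, amounts are DM mass * %/100 and
    digestibility follows :func:`apparent_digestibility`. A nutrient
    present in the diet but missing from the fecal profile is skipped with
    a log message. When ``diet`` is None each intake record's own
    ``diet`` reference is used (required then on every record).
    """
    intake_map = {(r.animal_id, r.period): r for r in intakes}
    fecal_map = {(r.animal_id, r.period): r for r in feces}
    only_intake = sorted(set(intake_map) - set(fecal_map))
    only_fecal = sorted(set(fecal_map) - set(intake_map))
    if only_intake or only_fecal:
        raise ValueError(
            "unmatched animal/period keys: "
            f"intake-only={only_intake}, fecal-only={only_fecal}"
        )

    results: list[DigestibilityResult] = []
    for key in sorted(intake_map):
        rec = intake_map[key]
        fec = fecal_map[key]
        d_spec = diet if diet is not None else rec.diet
        if d_spec is None:
            raise ValueError(f"no diet available for record {key}")
        diet_nutrients = d_spec.profile.as_dict()
        fecal_nutrients = fec.nutrient_conc.as_dict()
        digest: dict[str, float] = {}
        nut_in: dict[str, float] = {}
        nut_out: dict[str, float] = {}
        # DM digestibility always comes from the DM masses themselves,
        # independent of any DM% assay row in the profiles
        if rec.dm_intake > 0:
            digest["dm"] = apparent_digestibility(rec.dm_intake, fec.fecal_dm)
            nut_in["dm"] = rec.dm_intake
            nut_out["dm"] = fec.fecal_dm
        for nutrient, pct in diet_nutrients.items():
            if nutrient == "dm":
                continue
            if nutrient == "ge":
                intake_amt = rec.dm_intake * pct  # cal/day per g -> kcal-scale; ratio only
                if fecal_nutrients.get("ge") is None:
                    logger.info("nutrient ge absent from fecal profile for %s; skipped", key)
                    continue
                excr_amt = fec.fecal_dm * fecal_nutrients["ge"]
            else:
                if nutrient not in fecal_nutrients:
                    logger.info(
                        "nutrient %s absent from fecal profile for %s; skipped",
                        nutrient, key,
                    )
                    continue
                intake_amt = rec.dm_intake * pct / 100.0
                excr_amt = fec.fecal_dm * fecal_nutrients[nutrient] / 100.0
            if intake_amt <= 0:
                logger.info("zero intake of %s for %s; skipped", nutrient, key)
                continue
            digest[nutrient] = apparent_digestibility(intake_amt, excr_amt)
            nut_in[nutrient] = intake_amt
            nut_out[nutrient] = excr_amt
        results.append(
            DigestibilityResult(
                animal_id=rec.animal_id,
                period=rec.period,
                digestibility=digest,
                nutrient_intake=nut_in,
                nutrient_excretion=nut_out,
            )
        )
    return results


def mean_digestibility(results: Sequence[DigestibilityResult]) -> dict[str, float]:
    """Equal-weight mean digestibility per nutrient across animal-periods."""
    if not results:
        return {}
    nutrients = sorted({n for r in results for n in r.digestibility})
    return {
        n: float(np.mean([r.digestibility[n] for r in results if n in r.digestibility]))
        for n in nutrients
    }
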