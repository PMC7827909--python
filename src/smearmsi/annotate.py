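"""Adduct-resolved metabolite annotation of differential m/z.

Each observed m/z is scanned exhaustively against every (metabolite,
adduct rule) pair of a frozen database; a pair is a hit when the
theoretical adduct m/z lies within ±tol (default 0.025 Da, inclusive).
The published filtering is then applied: hits whose metabolite lacks a
KEGG identifier or the endogenous/essential attribute are dropped, and an
observed m/z is reported only when exactly one metabolite survives
("single hits"; multiple matches, including isobars, are discarded).
Uniqueness is judged at metabolite level: one compound reachable through
two adduct rules still counts as a single hit, and the adduct with the
smaller absolute mass error is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemmass import AdductRule, adduct_mz
from .msidata import MetaboliteRecord

__all__ = [
    "AnnotationHit",
    "match_mz",
    "filter_annotations",
    "annotate_diff_table",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.025  # Da


@dataclass(frozen=True)
class AnnotationHit:
    """One (observed m/z, adduct rule, metabolite) match."""

    observed_mz: float
    rule: AdductRule
    metabolite: MetaboliteRecord
    theoretical_mz: float
    mass_error: float  # signed, observed - theoretical
    unique: bool = False


def match_mz(
    observed_mz: float,
    db: Sequence[MetaboliteRecord],
    rules: Sequence[AdductRule],
    tol: float = DEFAULT_TOLERANCE,
    polarity: int | None = None,
) -> list[AnnotationHit]:
    """All (metabolite, rule) pairs within ±tol of an observed m/z,
    sorted by absolute mass error.

    ``polarity`` restricts the rule set to one ionization mode; the rule
    set must be nonempty after filtering.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if polarity is not None:
        rules = [r for r in rules if r.polarity == polarity]
    if not rules:
        raise ValueError("empty adduct rule set")
    hits = []
    for met in db:
        for rule in rules:
            theo = adduct_mz(met.monoisotopic_mass, rule)
            err = observed_mz - theo
            if abs(err) <= tol:
                hits.append(AnnotationHit(observed_mz, rule, met, theo, err))
    hits.sort(key=lambda h: abs(h.mass_error))
    return hits


def filter_annotations(hits: Sequence[AnnotationHit]) -> list[AnnotationHit]:
    """Apply the single-hit endogenous/KEGG filter to the hits of ONE
    observed m/z.

    Drops hits whose metabolite has no KEGG id or is not flagged
    endogenous/essential; keeps the m/z only if exactly one metabolite
    remains, reporting its best-error adduct with ``unique=True``.
    """
    eligible = [h for h in hits
                if h.metabolite.kegg_id and h.metabolite.endogenous_or_essential]
    metabolites = {h.metabolite.hmdb_id for h in eligible}
    if len(metabolites) != 1:
        return []
    best = min(eligible, key=lambda h: abs(h.mass_error))
    return [AnnotationHit(best.observed_mz, best.rule, best.metabolite,
                          best.theoretical_mz, best.mass_error, unique=True)]


def annotate_diff_table(
    diff: pd.DataFrame,
    db: Sequence[MetaboliteRecord],
    rules: Sequence[AdductRule],
    tol: float = DEFAULT_TOLERANCE,
    polarity: int | None = None,
) -> pd.DataFrame:
    """Join significant differential m/z with their unique annotations.

    Produces the published report schema: m/z, adduct, KEGG id,
    metabolite, cell/plasma fold change, instrument setting, cell type.
    Rows without a surviving single hit are omitted.
    """
    rows = []
    sig = diff[diff["significant"]] if "significant" in diff.columns else diff
    for _, row in sig.iterrows():
        hits = filter_annotations(match_mz(row["mz"], db, rules, tol, polarity))
        if not hits:
            continue
        h = hits[0]
        rows.append(
            {
                "mz": row["mz"],
                "adduct": h.rule.name,
                "kegg_id": h.metabolite.kegg_id,
                "metabolite": h.metabolite.name,
                "cell_plasma_ratio": row.get("fold_change", np.nan),
                "setting": row.get("setting", ""),
                "cell_type": row.get("cell_type", ""),
                "mass_error": h.mass_error,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mz", "adduct", "kegg_id", "metabolite", "cell_plasma_ratio",
                 "setting", "cell_type", "mass_error"],
    )
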