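"""Ortholog-group categorization, species summaries, and correlations.

Consumes precomputed ortholog-group membership tables
(``group_id<TAB>species<TAB>gene_id``) and classifies each group from the
set of species it contains: species-specific (exactly one species),
lineage-specific (all members inside a configured lineage, here the
lepidopteran trio, with at least two of them), universally shared across
the configured insect set (1:1 when single-copy everywhere, N:N with
paralogs), or "other".  Per-species gene/group counts and paralog-expansion
ratios follow directly.  The genome-size correlation analysis is a plain
Pearson r with a t-distributed two-sided p.
"""

from __future__ import annotations

from typing import Dict, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CATEGORY_SPECIES = "species_specific"
CATEGORY_LINEAGE = "lineage_specific"
CATEGORY_COMMON_11 = "insect_common_1to1"
CATEGORY_COMMON_NN = "insect_common_NtoN"
CATEGORY_OTHER = "other"


def categorize_groups(
    table: pd.DataFrame, insect_set: Set[str], lineage_set: Set[str]
) -> pd.DataFrame:
    """One category per group, a total function of its species set.

    Returns a frame (group_id, category, subcategory): subcategory names
    the species for species-specific groups and the joined species pair
    for two-species lineage groups.
    """
    if (table.groupby("gene_id").group_id.nunique() > 1).any():
        raise ValueError("a gene appears in more than one ortholog group")
    rows = []
    for gid, sub in table.groupby("group_id", sort=True):
        species = set(sub.species)
        if not species:
            raise ValueError(f"group {gid} has no members")
        counts = sub.groupby("species").size()
        if len(species) == 1:
            cat, subcat = CATEGORY_SPECIES, next(iter(species))
        elif species <= lineage_set and len(species) >= 2:
            subcat = "-".join(sorted(species)) if len(species) < len(lineage_set) else ""
            cat = CATEGORY_LINEAGE
        elif insect_set <= species:
            cat = CATEGORY_COMMON_11 if (counts.loc[sorted(insect_set)] == 1).all() \
                else CATEGORY_COMMON_NN
            subcat = ""
        else:
            cat, subcat = CATEGORY_OTHER, ""
        rows.append(dict(group_id=gid, category=cat, subcategory=subcat))
    return pd.DataFrame(rows)


def summarize_species(
    table: pd.DataFrame, categories: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], float]]:
    """Per species x category group/gene counts and paralog ratios.

    ``genes_per_group`` is n_genes / n_ortholog_groups (NaN when a species
    has no groups in a category).  The second return value holds pairwise
    ratios of species-specific group counts (species_a count / species_b
    count).
    """
    merged = table.merge(categories, on="group_id")
    rows = []
    for (sp, cat), sub in merged.groupby(["species", "category"], sort=True):
        n_groups = sub.group_id.nunique()
        n_genes = len(sub)
        rows.append(dict(
            species=sp, category=cat, n_ortholog_groups=n_groups, n_genes=n_genes,
            genes_per_group=round(n_genes / n_groups, 2) if n_groups else np.nan,
        ))
    summary = pd.DataFrame(rows)
    spec = summary[summary.category == CATEGORY_SPECIES].set_index("species")
    ratios: Dict[Tuple[str, str], float] = {}
    for a in spec.index:
        for b in spec.index:
            if a != b and spec.loc[b, "n_ortholog_groups"]:
                ratios[(a, b)] = round(
                    spec.loc[a, "n_ortholog_groups"] / spec.loc[b, "n_ortholog_groups"], 1
                )
    return summary, ratios


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n-2 df)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
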