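"""Consensus peptide→KO mapping and rank-based KEGG-pathway enrichment.

A peptide inherits a KEGG ortholog (KO) only under strict consensus: if
every protein in its group carries the *same* KO it is annotated with that
KO; any disagreement, or any group member lacking a KO, leaves the peptide
unannotated.  The mapped peptides join KO→pathway membership to form
pathway peptide sets, which are scored per sample with a GSVA-style
rank-based enrichment statistic and tested for group effects.

The enrichment score is the kernel-free rank variant of gene set variation
analysis: intensities are log2(x+1)-transformed, ranked within each sample,
converted to the symmetric rank statistic r = rank − (p+1)/2, and a
Kolmogorov–Smirnov-like random walk is taken down the list ordered by
decreasing expression — inside-set steps weighted by |r|^τ (τ=1, normalized
to sum to 1), outside-set steps by −1/(p−m).  The score is the walk's
maximum deviation from zero, signed (default), or the sum of its maximum
positive and negative deviations ("diff"); either is bounded in [−1, 1].
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peptide_io import PeptideObservation

__all__ = [
    "consensus_ko",
    "build_peptide_ko_db",
    "load_ko_pathway_table",
    "pathway_peptide_sets",
    "gsva_scores",
    "enrichment_significance",
]


def consensus_ko(
    ob: PeptideObservation,
    protein_ko: Mapping[str, str | None],
    dedup_map: Mapping[str, str] | None = None,
) -> str | None:
    """Strict-consensus KO for one peptide's protein group.

    Returns the KO shared by *every* group member, or None if any member
    disagrees, lacks a KO, or is absent from the table.  Invariant to group
    order and duplication.
    """
    dedup_map = dedup_map or {}
    kos = {
        protein_ko.get(dedup_map.get(pid, pid)) for pid in set(ob.protein_group)
    }
    if len(kos) == 1:
        (ko,) = kos
        return ko  # may be None: a uniformly KO-less group is unannotated
    return None


def build_peptide_ko_db(
    observations: Sequence[PeptideObservation],
    protein_ko: Mapping[str, str | None],
    dedup_map: Mapping[str, str] | None = None,
    out_path=None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Peptide-to-KEGG map over a batch of (filtered) observations.

    Returns the sequence→KO dict (consensus-mappable peptides only) and a
    two-column (peptide, ko) table in deterministic (sorted) order, suitable
    as a pepFunk-style peptide-to-KEGG database; written as TSV when
    ``out_path`` is given.
    """
    ko_map: dict[str, str] = {}
    for ob in observations:
        ko = consensus_ko(ob, protein_ko, dedup_map)
        if ko is not None:
            ko_map[ob.sequence] = ko
    table = pd.DataFrame(
        sorted(ko_map.items()), columns=["peptide", "ko"]
    )
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return ko_map, table


def load_ko_pathway_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ko", "pathway_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: KO→pathway table missing column {col!r}")
    return df


def pathway_peptide_sets(
    ko_map: Mapping[str, str],
    ko_to_pathway: pd.DataFrame | Mapping[str, set[str]],
    min_size: int = 5,
) -> dict[str, set[str]]:
    """Join the peptide→KO map against KO→pathway membership.

    A peptide joins every pathway containing its KO; pathways with fewer
    than ``min_size`` peptides are dropped.
    """
    if isinstance(ko_to_pathway, pd.DataFrame):
        pathways_of: dict[str, set[str]] = {}
        for row in ko_to_pathway.itertuples():
            pathways_of.setdefault(row.ko, set()).add(row.pathway_id)
    else:
        pathways_of = {k: set(v) for k, v in ko_to_pathway.items()}
    sets: dict[str, set[str]] = {}
    for peptide, ko in ko_map.items():
        for pathway in pathways_of.get(ko, ()):
            sets.setdefault(pathway, set()).add(peptide)
    return {p: s for p, s in sets.items() if len(s) >= min_size}


def _sample_walk_scores(
    x: np.ndarray,
    labels: np.ndarray,
    set_masks: np.ndarray,
    tau: float,
    method: str,
) -> np.ndarray:
    """Enrichment scores for one sample; set_masks is (n_sets, p) boolean."""
    p = x.size
    ranks = stats.rankdata(x)  # average ties
    weight = np.abs(ranks - (p + 1) / 2.0) ** tau
    # walk order: decreasing expression, ties broken by label for determinism
    order = np.lexsort((labels, -x))
    scores = np.empty(set_masks.shape[0])
    for k, mask in enumerate(set_masks):
        m = int(mask.sum())
        in_set = mask[order]
        w = np.where(in_set, weight[order], 0.0)
        w_total = w.sum()
        if w_total <= 0:  # all in-set statistics zero: flat walk
            inside = np.zeros(p)
        else:
            inside = np.cumsum(w) / w_total
        if m < p:
            outside = np.cumsum(~in_set) / (p - m)
        else:
            # degenerate set covering every peptide: compare against the
            # uniform ECDF so the walk stays defined
            outside = np.arange(1, p + 1) / p
        walk = inside - outside
        if method == "maxdev":
            scores[k] = walk[np.argmax(np.abs(walk))]
        elif method == "diff":
            scores[k] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
        else:
            raise ValueError(f"unknown score method {method!r}")
    return scores


def gsva_scores(
    intensity: pd.DataFrame,
    pathway_sets: Mapping[str, set[str]],
    tau: float = 1.0,
    method: str = "maxdev",
) -> pd.DataFrame:
    """GSVA-style pathway × sample enrichment scores.

    ``intensity`` is a peptide × sample matrix of raw intensities
    (log2(x+1) is applied internally; scoring is rank-based, hence invariant
    to any strictly monotone per-sample transform).  Requires ≥3 samples.
    Pathway sets disjoint from the matrix rows are skipped with a warning.
    """
    if intensity.shape[1] < 3:
        raise ValueError("gsva_scores requires at least 3 samples")
    peptides = intensity.index.to_numpy()
    labels = np.argsort(np.argsort(peptides))  # stable name order for ties
    masks, kept = [], []
    for pathway in sorted(pathway_sets):
        mask = np.isin(peptides, sorted(pathway_sets[pathway]))
        if not mask.any():
            warnings.warn(
                f"pathway {pathway!r} shares no peptides with the matrix; skipped",
                stacklevel=2,
            )
            continue
        masks.append(mask)
        kept.append(pathway)
    if not kept:
        return pd.DataFrame(index=[], columns=intensity.columns, dtype=float)
    set_masks = np.vstack(masks)
    x = np.log2(intensity.to_numpy(dtype=float) + 1.0)
    out = np.column_stack(
        [
            _sample_walk_scores(x[:, j], labels, set_masks, tau, method)
            for j in range(x.shape[1])
        ]
    )
    return pd.DataFrame(out, index=kept, columns=intensity.columns)


def enrichment_significance(
    scores: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 1e-6,
) -> pd.DataFrame:
    """Per-pathway group-effect test on enrichment scores.

    One-way ANOVA of each pathway's scores across the sample group labels,
    with Benjamini–Hochberg adjustment over pathways.  Requires ≥2 groups
    with ≥2 samples each.  Returns a table indexed by pathway with columns
    ``p_value``, ``p_adjusted`` and ``significant`` (adjusted p < alpha,
    default 1e-6).
    """
    by_label: dict[str, list[str]] = {}
    for sample in scores.columns:
        if sample not in groups:
            raise ValueError(f"sample {sample!r} has no group label")
        by_label.setdefault(groups[sample], []).append(sample)
    if len(by_label) < 2 or any(len(s) < 2 for s in by_label.values()):
        raise ValueError("need ≥2 groups with ≥2 samples each")
    pvals = np.empty(len(scores.index))
    for i, (_, row) in enumerate(scores.iterrows()):
        arrays = [row[cols].to_numpy(dtype=float) for cols in by_label.values()]
        flat = np.concatenate(arrays)
        if np.ptp(flat) == 0:  # identical scores: no evidence of an effect
            pvals[i] = 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals[i] = stats.f_oneway(*arrays).pvalue
        if not np.isfinite(pvals[i]):
            pvals[i] = 1.0
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "p_value": pvals,
            "p_adjusted": adjusted,
            "significant": adjusted < alpha,
        },
        index=scores.index,
    )
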