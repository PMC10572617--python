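"""Hallmark-of-cancer profiling of differentially activated circuits.

Circuit effector genes carry text-mining association scores to the ten
canonical hallmarks of cancer; associations at score >= 0.15 (inclusive, the
95th-percentile operating point of the score distribution) are retained.  A
circuit contributes to every hallmark that any of its effector genes passes
the cutoff for; circuits whose effector genes pass no hallmark are tallied
as "unannotated".  Counts and fractions are reported per condition.
"""

from __future__ import annotations

import logging

import pandas as pd

from .graphs import CircuitCatalog

logger = logging.getLogger(__name__)

__all__ = ["HALLMARKS", "load_annotations", "filter_chat", "hallmark_profile"]

#: the ten canonical hallmarks of cancer
HALLMARKS = (
    "sustaining proliferative signaling",
    "evading growth suppressors",
    "resisting cell death",
    "enabling replicative immortality",
    "inducing angiogenesis",
    "activating invasion and metastasis",
    "genome instability and mutation",
    "tumor-promoting inflammation",
    "deregulating cellular energetics",
    "avoiding immune destruction",
)

UNANNOTATED = "unannotated"


def load_annotations(source) -> pd.DataFrame:
    """Read a ``gene  hallmark  score`` TSV of effector-hallmark scores."""
    df = pd.read_csv(source, sep="\t", dtype={"gene": str, "hallmark": str})
    missing = {"gene", "hallmark", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if (df["score"] < 0).any():
        raise ValueError("hallmark scores must be >= 0")
    if df.duplicated(["gene", "hallmark"]).any():
        raise ValueError("duplicate (gene, hallmark) annotation rows")
    return df


def filter_chat(annotations: pd.DataFrame, cutoff: float = 0.15) -> pd.DataFrame:
    """Keep associations with score >= cutoff (inclusive)."""
    if annotations.empty:
        logger.warning("empty hallmark annotation table")
        return annotations
    return annotations[annotations["score"] >= cutoff].reset_index(drop=True)


def hallmark_profile(
    significant: dict[str, list[str]],
    catalog: CircuitCatalog,
    annotations: pd.DataFrame,
    cutoff: float = 0.15,
) -> pd.DataFrame:
    """Per-condition hallmark counts/fractions over significant circuits.

    ``significant`` maps condition -> circuit_ids.  The fraction denominator
    is the number of significant circuits in the condition; a circuit with
    multiple passing hallmarks counts once per hallmark, so fractions can sum
    above 1.
    """
    kept = filter_chat(annotations, cutoff)
    gene_hallmarks: dict[str, set[str]] = {}
    for _, row in kept.iterrows():
        gene_hallmarks.setdefault(row["gene"], set()).add(row["hallmark"])
    extra = sorted(set(kept["hallmark"]) - set(HALLMARKS)) if not kept.empty else []
    categories = list(HALLMARKS) + extra + [UNANNOTATED]
    rows = []
    for condition in sorted(significant):
        circuit_ids = significant[condition]
        counts = {h: 0 for h in categories}
        for cid in circuit_ids:
            circuit = catalog[cid]
            hits = set()
            for gene in circuit.effector_genes:
                hits |= gene_hallmarks.get(gene, set())
            if hits:
                for h in hits:
                    counts[h] += 1
            else:
                counts[UNANNOTATED] += 1
        denom = len(circuit_ids)
        for h in categories:
            rows.append(
                {
                    "condition": condition,
                    "hallmark": h,
                    "count": counts[h],
                    "fraction": counts[h] / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "hallmark", "count", "fraction"])
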