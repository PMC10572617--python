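"""Transcription-factor target enrichment analysis (TFTEA).

Transcription factors are often too lowly expressed for their mRNA to reflect
their activity, so activity is estimated indirectly: genes are ranked by a
differential statistic (moderated t by default) and each TF's regulon
(curated target set, graded A-E by evidence confidence) is tested for
enrichment toward either end of the ranking with a univariate logistic
regression of target membership on the normalized rank r in [0, 1]
(0 = most down-regulated, 1 = most up-regulated).  The slope is the reported
log-odds ratio (LOR); positive LOR means targets pile up among up-regulated
genes.  BH correction is applied across TFs per contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "Regulon",
    "EnrichmentResult",
    "load_regulons",
    "rank_genes",
    "tftea_enrich",
    "tftea_all",
    "summarize_contrasts",
]

GRADES = ("A", "B", "C", "D", "E")
LOR_CAP = 50.0  # reported |lor| under complete separation


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: tuple[str, ...]
    confidences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"regulon {self.tf!r} has no targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.tf!r} has duplicate targets")
        if len(self.confidences) != len(self.targets):
            raise ValueError(f"regulon {self.tf!r}: confidences misaligned")


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    lor: float
    p: float
    n_targets: int
    flag: str = ""

    @property
    def direction(self) -> str:
        return "up" if self.lor > 0 else "down"


def _parse_gmt(lines) -> list[tuple[str, str, str]]:
    triples = []
    for i, line in enumerate(lines):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {i + 1}: expected tf, description, targets")
        tf = parts[0]
        for target in parts[2:]:
            if target:
                triples.append((tf, target, "A"))  # GMT carries no grades
    return triples


def _parse_tsv(lines) -> list[tuple[str, str, str]]:
    triples = []
    for i, line in enumerate(lines):
        parts = line.rstrip("\n").split("\t")
        if i == 0 and parts[0].lower() in {"tf", "source"}:
            continue  # header
        if len(parts) < 2:
            raise ValueError(f"regulon TSV line {i + 1}: expected tf, target[, confidence]")
        grade = parts[2].strip().upper() if len(parts) > 2 and parts[2].strip() else "A"
        if grade not in GRADES:
            raise ValueError(f"regulon TSV line {i + 1}: malformed grade token {parts[2]!r}")
        triples.append((parts[0], parts[1], grade))
    return triples


def load_regulons(
    source,
    fmt: str | None = None,
    min_confidence: str = "C",
    min_targets: int = 5,
) -> list[Regulon]:
    """Load regulons from GMT (``tf  description  target...``) or TSV
    (``tf  target  confidence``) form.

    Interactions graded worse than ``min_confidence`` are dropped; regulons
    left with fewer than ``min_targets`` targets are dropped with a log entry.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "")
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
        name = str(source)
    if fmt is None:
        fmt = "gmt" if name.endswith(".gmt") else "tsv"
    if min_confidence.upper() not in GRADES:
        raise ValueError(f"malformed grade token {min_confidence!r}")
    cutoff = GRADES.index(min_confidence.upper())
    triples = _parse_gmt(lines) if fmt == "gmt" else _parse_tsv(lines)
    by_tf: dict[str, dict[str, str]] = {}
    for tf, target, grade in triples:
        kept = by_tf.setdefault(tf, {})
        if GRADES.index(grade) <= cutoff:
            kept[target] = grade
    regulons = []
    for tf in sorted(by_tf):
        kept = by_tf[tf]
        if len(kept) < min_targets:
            logger.info("dropping regulon %s: %d targets after filtering", tf, len(kept))
            continue
        targets = tuple(sorted(kept))
        regulons.append(Regulon(tf=tf, targets=targets, confidences=tuple(kept[t] for t in targets)))
    return regulons


def rank_genes(stat: pd.Series) -> pd.Series:
    """Normalized rank r in [0, 1] of a differential statistic.

    r = 0 for the most down-regulated gene, 1 for the most up-regulated;
    ranks are evenly spaced; ties broken deterministically by gene id.
    """
    vals = stat.to_numpy(dtype=float)
    order = np.lexsort((stat.index.to_numpy(), vals))
    m = len(vals)
    r = np.empty(m)
    r[order] = np.arange(m) / (m - 1) if m > 1 else 0.5
    return pd.Series(r, index=stat.index, name="rank")


def tftea_enrich(
    ranked: pd.Series,
    regulon: Regulon,
    min_targets: int = 5,
) -> EnrichmentResult:
    """Logistic-regression enrichment of one regulon on the ranked genes.

    Fits P(target | r) = logistic(a + lor * r); reports the slope and its
    Wald p.  Complete separation yields a capped |lor| with a flag; an
    unusable regulon (too few targets in the universe, or covering every
    gene) yields NaN with a reason flag.
    """
    member = pd.Series(ranked.index.isin(regulon.targets), index=ranked.index)
    n_in = int(member.sum())
    if n_in < min_targets:
        return EnrichmentResult(regulon.tf, np.nan, np.nan, n_in, flag="too_few_targets")
    if n_in == len(ranked):
        return EnrichmentResult(regulon.tf, np.nan, np.nan, n_in, flag="covers_universe")
    y = member.to_numpy(dtype=float)
    X = sm.add_constant(ranked.to_numpy(dtype=float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        lor = float(res.params[1])
        p = float(res.pvalues[1])
        if not np.isfinite(lor) or abs(lor) > LOR_CAP:
            raise ValueError("separation")
        return EnrichmentResult(regulon.tf, lor, p, n_in)
    except Exception:  # perfect separation / non-convergence
        direction = 1.0 if ranked[member].mean() >= ranked.mean() else -1.0
        return EnrichmentResult(regulon.tf, direction * LOR_CAP, 0.0, n_in, flag="separation")


def tftea_all(
    ranked: pd.Series,
    regulons: list[Regulon],
    alpha: float = 0.05,
    min_targets: int = 5,
) -> pd.DataFrame:
    """Enrichment of every regulon with BH correction across testable TFs."""
    results = [tftea_enrich(ranked, reg, min_targets=min_targets) for reg in regulons]
    if not results:
        logger.warning("no usable regulons; empty enrichment table")
        return pd.DataFrame(columns=["tf", "lor", "p", "fdr", "n_targets", "direction", "flag"])
    table = pd.DataFrame(
        {
            "tf": [r.tf for r in results],
            "lor": [r.lor for r in results],
            "p": [r.p for r in results],
            "n_targets": [r.n_targets for r in results],
            "flag": [r.flag for r in results],
        }
    )
    table["fdr"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "fdr"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["direction"] = np.where(table["lor"] > 0, "up", "down")
    table["significant"] = table["fdr"] < alpha
    return table.sort_values(["fdr", "p", "tf"], kind="stable").reset_index(drop=True)


def summarize_contrasts(tables: dict[str, pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Cross-contrast summary: per TF the number of contrasts where it was
    significant and the average LOR / FDR over those contrasts."""
    rows = []
    all_tfs = sorted({tf for tab in tables.values() for tf in tab["tf"]})
    for tf in all_tfs:
        sig = []
        for tab in tables.values():
            hit = tab[(tab["tf"] == tf) & (tab["fdr"] < alpha)]
            if len(hit):
                sig.append(hit.iloc[0])
        if sig:
            rows.append(
                {
                    "tf": tf,
                    "n": len(sig),
                    "lor": float(np.mean([h["lor"] for h in sig])),
                    "fdr": float(np.mean([h["fdr"] for h in sig])),
                }
            )
    return pd.DataFrame(rows, columns=["tf", "n", "lor", "fdr"])
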