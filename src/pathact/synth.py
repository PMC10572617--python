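"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical shape of the study inputs: random
signed pathway graphs decomposed into effector circuits; RNA-seq-like
negative-binomial counts with log-normal gene abundances, library-size
variation and a (by default condition-orthogonal) batch effect; planted
up/down shifts on the member genes of selected circuits; survival times from
a Cox model driven by standardized circuit activities with independent
uniform censoring; and TF regulons whose targets are tilted toward the top
of the true effect ranking.  A fixed seed yields byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import (
    CircuitCatalog,
    PathwayGraph,
    PathwayNode,
    SignedEdge,
    extract_circuits,
    merge_catalogs,
    positive_influence_nodes,
)
from .hallmarks import HALLMARKS
from .preprocess import impute_missing, log_cpm, rescale_unit, tmm_factors
from .propagation import ActivityMatrix, PropagationConfig, compute_activity_matrix, propagate_circuit
from .tftea import Regulon

__all__ = [
    "SimulationSpec",
    "make_toy_pathways",
    "simulate_counts",
    "simulate_survival",
    "make_regulons",
    "write_bundle",
]

_FLOAT_FMT = "%.10g"


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults give a small two-arm
    cohort (30 cases vs 30 controls) with moderate RNA-seq overdispersion."""

    seed: int = 0
    # pathway topology
    n_pathways: int = 5
    nodes_per_pathway: tuple[int, int] = (6, 12)
    cycle_prob: float = 0.15
    inhibition_prob: float = 0.2
    genes_per_node: tuple[int, int] = (1, 3)
    # expression
    n_background_genes: int = 1500
    n_case: int = 30
    n_control: int = 30
    nb_dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_planted_circuits: int = 3
    planted_log2_effect: float = 1.5
    n_batches: int = 2
    batch_effect_sd: float = 0.1
    confound_batch: bool = False
    # survival
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    n_survival_circuits: int = 1
    survival_beta: float = 1.0
    censoring_fraction: float = 0.3
    # regulons
    n_tfs: int = 20
    targets_per_tf: int = 30
    n_planted_tfs: int = 2
    enrichment_tilt: float = 40.0

    def __post_init__(self) -> None:
        for p in (self.cycle_prob, self.inhibition_prob, self.censoring_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per arm")


def _stage_rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stage,)))


def _gain(circuit) -> float:
    """Effector-signal swing when positive-influence nodes go 0.1 -> 0.9
    (other nodes held at 0.5); zero for circuits pinned by inhibitory cycles."""
    pos = positive_influence_nodes(circuit)
    order = sorted(circuit.member_nodes)
    signals = []
    for level in (0.1, 0.9):
        vals = pd.DataFrame(
            {"v": [level if n in pos else 0.5 for n in order]}, index=order
        )
        s, _ = propagate_circuit(circuit, vals)
        signals.append(float(s[0]))
    return signals[1] - signals[0]


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


def make_toy_pathways(spec: SimulationSpec) -> tuple[list[PathwayGraph], CircuitCatalog, dict]:
    """Random signed pathway graphs, their circuit catalog, and a truth record
    mapping every circuit to its member genes."""
    rng = _stage_rng(spec, 0)
    graphs = []
    gene_counter = 0
    for p in range(spec.n_pathways):
        pid = f"P{p + 1:03d}"
        n_nodes = int(rng.integers(spec.nodes_per_pathway[0], spec.nodes_per_pathway[1] + 1))
        node_ids = [f"{pid}N{i:02d}" for i in range(n_nodes)]
        edges: set[tuple[str, str]] = set()
        # forward skeleton over a fixed topological order: every node after
        # the first receives 1-2 earlier sources, so the graph drains forward
        # while leaving several sinks (effectors) behind
        for j in range(1, n_nodes):
            n_in = int(rng.integers(1, 3))
            sources = rng.choice(np.arange(j), size=min(n_in, j), replace=False)
            for i in sources:
                edges.add((node_ids[int(i)], node_ids[j]))
        # optional back-edges introduce cycles; sinks never emit one, so
        # every pathway keeps its effectors
        sinks = {tgt for tgt in node_ids} - {src for src, _ in edges}
        candidates = [nid for nid in node_ids[1:] if nid not in sinks]
        n_back = rng.binomial(n_nodes, spec.cycle_prob)
        for _ in range(n_back):
            if not candidates:
                break
            src = candidates[int(rng.integers(len(candidates)))]
            j = node_ids.index(src)
            i = int(rng.integers(0, j))
            edges.add((src, node_ids[i]))
        nodes = {}
        for nid in node_ids:
            k = int(rng.integers(spec.genes_per_node[0], spec.genes_per_node[1] + 1))
            genes = tuple(f"G{gene_counter + g:05d}" for g in range(k))
            gene_counter += k
            nodes[nid] = PathwayNode(node_id=nid, genes=genes, label=nid)
        signed = [
            SignedEdge(src, tgt, -1 if rng.random() < spec.inhibition_prob else 1)
            for src, tgt in sorted(edges)
        ]
        graphs.append(PathwayGraph(pathway_id=pid, name=f"toy pathway {pid}", nodes=nodes, edges=signed))
    catalog = merge_catalogs(extract_circuits(g) for g in graphs)
    truth = {
        "circuits": {
            c.circuit_id: {"effector": c.effector, "genes": sorted(c.genes)} for c in catalog
        }
    }
    return graphs, catalog, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    spec: SimulationSpec,
    catalog: CircuitCatalog,
    truth: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Negative-binomial counts with planted circuit effects and batch noise.

    Returns (counts genes x samples, design table, truth updated with the
    planted circuits and per-gene true log2 effects).
    """
    rng = _stage_rng(spec, 1)
    pathway_genes = sorted(catalog.all_genes)
    background = [f"B{i:05d}" for i in range(spec.n_background_genes)]
    genes = pathway_genes + background
    n_genes = len(genes)

    samples = [f"case{i + 1:03d}" for i in range(spec.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(spec.n_control)
    ]
    condition = ["case"] * spec.n_case + ["control"] * spec.n_control

    # planted circuits: one per randomly chosen pathway (pathways share no
    # genes, so planted effects never collide), alternating up/down.  Only
    # genes of positive-influence nodes are shifted: raising them provably
    # raises the effector signal, so the recorded direction is ground truth.
    by_pathway: dict[str, list[str]] = {}
    for c in catalog:
        by_pathway.setdefault(c.pathway_id, []).append(c.circuit_id)
    # within a pathway, plant the most responsive circuit: the one whose
    # effector signal moves most when its positive-influence nodes swing
    # (inhibitory cycles can pin a circuit near zero regardless of input);
    # pathways without any responsive circuit are skipped
    gains = {c.circuit_id: _gain(c) for c in catalog}
    pids = [p for p in sorted(by_pathway) if max(gains[cid] for cid in by_pathway[p]) > 0.05]
    n_planted = min(spec.n_planted_circuits, len(pids))
    chosen = [pids[i] for i in sorted(rng.choice(len(pids), size=n_planted, replace=False))]
    planted_ids = [max(by_pathway[p], key=lambda cid: (gains[cid], cid)) for p in chosen]
    gene_effect = pd.Series(0.0, index=genes)
    planted = {}
    for k, cid in enumerate(planted_ids):
        sign = 1.0 if k % 2 == 0 else -1.0
        effect = sign * spec.planted_log2_effect
        circuit = catalog[cid]
        target_nodes = positive_influence_nodes(circuit)
        shifted = sorted({g for n in target_nodes for g in circuit.node_genes[n]})
        for g in shifted:
            gene_effect[g] = effect
        planted[cid] = {
            "log2_effect": effect,
            "direction": "up" if sign > 0 else "down",
            "genes": shifted,
        }

    # batch labels: round-robin within each arm keeps batch orthogonal to
    # condition; the confounded variant reuses the condition label
    if spec.confound_batch:
        batch = list(condition)
    else:
        batch = [f"site{(i % spec.n_batches) + 1}" for i in range(spec.n_case)] + [
            f"site{(i % spec.n_batches) + 1}" for i in range(spec.n_control)
        ]

    log2_base = rng.normal(np.log2(150.0), 1.2, size=n_genes)
    batch_levels = sorted(set(batch))
    batch_shift = {b: rng.normal(0.0, spec.batch_effect_sd, size=n_genes) for b in batch_levels}
    lib_sizes = rng.uniform(spec.lib_size_range[0], spec.lib_size_range[1], size=len(samples))

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    eff = gene_effect.to_numpy()
    for j, (sample, cond, b) in enumerate(zip(samples, condition, batch)):
        log2_mu = log2_base + batch_shift[b] + (eff if cond == "case" else 0.0)
        rel = 2.0 ** log2_mu
        mu = rel / rel.sum() * lib_sizes[j]
        if spec.nb_dispersion < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / spec.nb_dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    design = pd.DataFrame({"sample_id": samples, "condition": condition, "batch": batch})
    truth = dict(truth)
    truth["planted_circuits"] = planted
    truth["gene_log2_effect"] = {g: float(e) for g, e in gene_effect.items() if e != 0.0}
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _calibrate_censoring(times: np.ndarray, u: np.ndarray, fraction: float) -> np.ndarray:
    """Uniform(0, c) censoring times with c bisected so the realized censored
    fraction is as close as possible to the request."""
    if fraction <= 0:
        return np.full_like(times, np.inf)
    lo, hi = 1e-6, float(times.max()) * 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = np.mean(mid * u < times)
        if frac > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * u


def simulate_survival(
    spec: SimulationSpec,
    activity: ActivityMatrix | pd.DataFrame,
    truth: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Clinical metadata driven by a Cox model on standardized activities.

    hazard_i = baseline * exp(sum_c beta_c * z(activity_c,i)); event times are
    exponential given the hazard; censoring is independent uniform calibrated
    to the requested fraction.  Emits the clinical dialect consumed by
    ``build_survival`` (days_to_death / days_to_last_follow_up /
    vital_status).
    """
    rng = _stage_rng(spec, 2)
    values = activity.values if isinstance(activity, ActivityMatrix) else activity
    usable = [cid for cid in values.index if values.loc[cid].std(ddof=1) > 0]
    n_surv = min(spec.n_survival_circuits, len(usable))
    chosen = [usable[i] for i in sorted(rng.choice(len(usable), size=n_surv, replace=False))]
    eta = np.zeros(values.shape[1])
    betas = {}
    for cid in chosen:
        x = values.loc[cid].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=1)
        eta += spec.survival_beta * z
        betas[cid] = spec.survival_beta
    hazard = spec.baseline_hazard * np.exp(eta)
    times = rng.exponential(1.0 / hazard)
    u = rng.uniform(size=times.size)
    censor = _calibrate_censoring(times, u, spec.censoring_fraction)
    observed = np.minimum(times, censor)
    event = times <= censor
    rows = []
    for sample, t, ev in zip(values.columns, observed, event):
        t = max(float(t), 0.01)
        if ev:
            # events may also carry an earlier follow-up entry; the survival
            # builder takes the max of the two fields
            follow = f"{0.9 * t:.2f}" if rng.random() < 0.5 else ""
            rows.append(
                {"sample_id": sample, "days_to_death": f"{t:.2f}", "days_to_last_follow_up": follow,
                 "vital_status": "Dead"}
            )
        else:
            rows.append(
                {"sample_id": sample, "days_to_death": "", "days_to_last_follow_up": f"{t:.2f}",
                 "vital_status": "Alive"}
            )
    clinical = pd.DataFrame(rows, columns=["sample_id", "days_to_death", "days_to_last_follow_up", "vital_status"])
    truth = dict(truth or {})
    truth["survival_betas"] = betas
    truth["censoring_fraction_requested"] = spec.censoring_fraction
    return clinical, truth


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------


def make_regulons(
    spec: SimulationSpec,
    true_effect: pd.Series,
    truth: dict | None = None,
) -> tuple[list[Regulon], dict]:
    """Regulons over the gene universe; planted TFs sample their targets with
    probability tilted toward the top of the true up-regulation ranking
    (tilt 0 = uniform = null)."""
    rng = _stage_rng(spec, 3)
    genes = np.array(sorted(true_effect.index))
    eff = true_effect.reindex(genes).to_numpy(dtype=float)
    # rank fraction: 0 = strongest up effect; ties broken by a random permutation
    perm = rng.permutation(len(genes))
    order = np.lexsort((perm, -eff))
    rank_frac = np.empty(len(genes))
    rank_frac[order] = np.arange(len(genes)) / max(len(genes) - 1, 1)

    regulons = []
    planted_tfs = []
    for t in range(spec.n_tfs):
        tf = f"TF{t + 1:02d}"
        planted = t < spec.n_planted_tfs and spec.enrichment_tilt > 0
        if planted:
            w = np.exp(-spec.enrichment_tilt * rank_frac)
            w /= w.sum()
            idx = rng.choice(len(genes), size=spec.targets_per_tf, replace=False, p=w)
            planted_tfs.append(tf)
        else:
            idx = rng.choice(len(genes), size=spec.targets_per_tf, replace=False)
        targets = tuple(sorted(genes[i] for i in idx))
        grades = tuple(rng.choice(["A", "B", "C"]) for _ in targets)
        regulons.append(Regulon(tf=tf, targets=targets, confidences=grades))
    truth = dict(truth or {})
    truth["planted_tfs"] = planted_tfs
    return regulons, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def graphs_to_tables(graphs: list[PathwayGraph]) -> tuple[pd.DataFrame, pd.DataFrame]:
    node_rows, edge_rows = [], []
    for g in graphs:
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            node_rows.append(
                {"pathway_id": g.pathway_id, "node_id": nid, "label": n.label,
                 "genes": ";".join(n.genes), "is_function": int(n.is_function)}
            )
        for e in g.edges:
            edge_rows.append(
                {"pathway_id": g.pathway_id, "source": e.source, "target": e.target,
                 "sign": f"{e.sign:+d}"}
            )
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)


def write_bundle(
    spec: SimulationSpec,
    out_dir,
    config: PropagationConfig = PropagationConfig(),
) -> dict:
    """Generate and write the full synthetic input bundle plus truth.json.

    Files: nodes.tsv, edges.tsv, counts.tsv, design.tsv, clinical.tsv,
    regulons.tsv, hallmarks.tsv, truth.json.  Returns {name: path} plus the
    truth record under "truth".
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graphs, catalog, truth = make_toy_pathways(spec)
    nodes_df, edges_df = graphs_to_tables(graphs)
    counts, design, truth = simulate_counts(spec, catalog, truth)

    factors = tmm_factors(counts)
    norm = log_cpm(counts, factors)
    scaled = rescale_unit(norm)
    scaled, _ = impute_missing(scaled, catalog.all_genes)
    activity = compute_activity_matrix(catalog, scaled, config)
    case_cols = [s for s in activity.values.columns if s.startswith("case")]
    clinical, truth = simulate_survival(spec, activity.values[case_cols], truth)

    true_effect = pd.Series(0.0, index=counts.index)
    for g, e in truth.get("gene_log2_effect", {}).items():
        true_effect[g] = e
    regulons, truth = make_regulons(spec, true_effect, truth)
    reg_rows = [
        {"tf": r.tf, "target": t, "confidence": c}
        for r in regulons
        for t, c in zip(r.targets, r.confidences)
    ]

    rng = _stage_rng(spec, 4)
    effector_genes = sorted({g for c in catalog for g in c.effector_genes})
    hm_rows = [
        {"gene": g, "hallmark": h, "score": round(float(rng.uniform(0.0, 0.3)), 4)}
        for g in effector_genes
        for h in HALLMARKS
    ]

    paths = {}
    for name, df, index in [
        ("nodes", nodes_df, False),
        ("edges", edges_df, False),
        ("counts", counts, True),
        ("design", design, False),
        ("clinical", clinical, False),
        ("regulons", pd.DataFrame(reg_rows), False),
        ("hallmarks", pd.DataFrame(hm_rows), False),
        ("catalog", catalog.to_frame(), False),
    ]:
        path = out / f"{name}.tsv"
        _write_tsv(df, path, index=index)
        paths[name] = str(path)
    truth["spec"] = asdict(spec)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = str(truth_path)
    return {"paths": paths, "truth": truth}
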