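"""Synthetic fixture generators with planted, recoverable structure.

Each generator emulates one of the table-level inputs the analysis consumes
— a multi-tissue consensus expression atlas, stage-ordered differentiation
profiles, a co-expressed bulk RNA-seq matrix, a scored protein-interaction
graph and differential-expression tables — at desk scale, together with the
ground truth that was planted, so every downstream classifier can be tested
for exact recovery without any external download.

Determinism: every generator derives an independent random substream from
``SynthConfig.seed`` and a per-generator stream id, so the same config
yields byte-identical outputs and adding one generator call never perturbs
another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, make_deg_table

__all__ = [
    "SynthConfig",
    "gen_consensus_nx",
    "gen_stagewise_profiles",
    "gen_module_expression",
    "gen_interaction_graph",
    "gen_deg_tables",
    "write_manifest",
]

# fixed stream ids: one per generator so substreams never collide
_STREAMS = {
    "consensus_nx": 1,
    "stagewise": 2,
    "modules": 3,
    "interactions": 4,
    "deg": 5,
}


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for all generators.

    ``expr_threshold`` is the "expressed" cutoff: a planted value counts as
    expressed iff it is strictly above this threshold, matching the NX > 1
    convention used throughout the analysis.
    """

    seed: int = 0
    n_background: int = 0
    noise_sd: float = 0.4
    expr_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def _gene_names(prefix: str, n: int, width: int = 5) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _expressed(rng: np.random.Generator, n: int, thr: float) -> np.ndarray:
    # strictly above the threshold, with headroom so rounding never flips it
    return thr + 0.5 + rng.uniform(0.0, 9.0, size=n)


def _silent(rng: np.random.Generator, n: int, thr: float) -> np.ndarray:
    return rng.uniform(0.0, thr, size=n)


# ---------------------------------------------------------------------------
# consensus NX atlas
# ---------------------------------------------------------------------------

def gen_consensus_nx(tissues: Sequence[str], restricted_genes: Sequence[str],
                     n_distractors: int, cfg: SynthConfig,
                     muscle_tissue: str = "skeletal muscle") -> ExpressionMatrix:
    """Generate a multi-tissue consensus NX table with planted muscle-only genes.

    Each restricted gene is expressed (NX > threshold) in the muscle tissue
    and silent everywhere else.  Distractors either are expressed in muscle
    plus at least one other tissue, or are silent in muscle — so the
    muscle-restricted signature filter recovers exactly the planted genes.
    """
    tissues = list(tissues)
    if muscle_tissue not in tissues:
        raise ValueError(f"{muscle_tissue!r} must be among the tissues")
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue names")
    restricted = [g.strip() for g in restricted_genes]
    if len(set(restricted)) != len(restricted):
        raise ValueError("duplicate gene names in restricted_genes")
    if n_distractors < 0:
        raise ValueError("n_distractors must be >= 0")

    rng = cfg.rng("consensus_nx")
    thr = cfg.expr_threshold
    muscle_col = tissues.index(muscle_tissue)
    n_t = len(tissues)

    genes = restricted + _gene_names("DIST", n_distractors)
    if len(set(genes)) != len(genes):
        raise ValueError("distractor names collide with restricted gene names")
    values = np.empty((len(genes), n_t))

    for i in range(len(restricted)):
        row = _silent(rng, n_t, thr)
        row[muscle_col] = _expressed(rng, 1, thr)[0]
        values[i] = row
    for j in range(n_distractors):
        i = len(restricted) + j
        row = _silent(rng, n_t, thr)
        if j % 2 == 0 and n_t > 1:
            # broadly expressed: muscle plus >= 1 other tissue
            row[muscle_col] = _expressed(rng, 1, thr)[0]
            others = [c for c in range(n_t) if c != muscle_col]
            extra = rng.choice(others, size=rng.integers(1, min(4, len(others)) + 1), replace=False)
            row[extra] = _expressed(rng, len(extra), thr)
        # else: silent in muscle (possibly expressed elsewhere)
        elif j % 4 == 1 and n_t > 1:
            others = [c for c in range(n_t) if c != muscle_col]
            extra = rng.choice(others, size=1)
            row[extra] = _expressed(rng, 1, thr)
        values[i] = row

    df = pd.DataFrame(values, index=genes, columns=tissues)
    return ExpressionMatrix(df, "nx")


# ---------------------------------------------------------------------------
# stage-ordered differentiation profiles
# ---------------------------------------------------------------------------

def gen_stagewise_profiles(stages: Sequence[str], onset_counts: Sequence[int],
                           maintenance_onset_counts: Sequence[int],
                           n_distractors: int, cfg: SynthConfig) -> pd.DataFrame:
    """Stage-mean expression profiles with planted onset / maintenance structure.

    For onset stage ``k``, planted genes are silent (<= threshold) at every
    earlier stage and expressed (> threshold) at stage ``k`` and all later
    stages.  Maintenance-planted genes additionally increase strictly from
    onset to the final stage; the remaining onset genes are guaranteed to
    violate strict monotonicity (while staying expressed).  Distractors
    either lapse below the threshold after being expressed, or are never
    expressed.

    Returns a genes x stages DataFrame of stage means on an FPKM-like scale.
    """
    stages = list(stages)
    n_s = len(stages)
    if n_s < 2:
        raise ValueError("need >= 2 ordered stages")
    if len(set(stages)) != n_s:
        raise ValueError("duplicate stage names")
    onset_counts = list(onset_counts)
    maint_counts = list(maintenance_onset_counts)
    if len(onset_counts) != n_s or len(maint_counts) != n_s:
        raise ValueError("need one onset count and one maintenance count per stage")
    if any(c < 0 for c in onset_counts + maint_counts) or n_distractors < 0:
        raise ValueError("counts must be >= 0")
    if any(m > o for m, o in zip(maint_counts, onset_counts)):
        raise ValueError("maintenance_onset_counts cannot exceed onset_counts")
    if maint_counts[-1] > 0:
        raise ValueError(
            "maintenance genes need at least one increasing step; "
            "final-stage onset cannot be maintenance-planted"
        )

    rng = cfg.rng("stagewise")
    thr = cfg.expr_threshold
    rows: list[np.ndarray] = []
    names: list[str] = []

    for k, stage in enumerate(stages):
        n_on, n_maint = onset_counts[k], maint_counts[k]
        tag = f"S{k + 1}"
        names += _gene_names(f"MAINT{tag}G", n_maint)
        names += _gene_names(f"ONSET{tag}G", n_on - n_maint)
        if n_maint:
            # strictly increasing from onset: cumulative positive steps
            start = thr + 0.5 + rng.uniform(0, 2, size=(n_maint, 1))
            steps = rng.uniform(0.5, 3.0, size=(n_maint, n_s - k - 1))
            expr = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
            block = np.concatenate([_silent(rng, (n_maint, k), thr) if k else
                                    np.empty((n_maint, 0)), expr], axis=1)
            rows.append(block)
        n_plain = n_on - n_maint
        if n_plain:
            expr = thr + 0.5 + rng.uniform(0.0, 9.0, size=(n_plain, n_s - k))
            if n_s - k >= 2:
                # force a non-increasing step while staying expressed
                hi = thr + 5.0 + rng.uniform(0, 4, size=n_plain)
                expr[:, -2] = hi
                expr[:, -1] = thr + 0.5 + rng.uniform(0, 2, size=n_plain)
            block = np.concatenate([_silent(rng, (n_plain, k), thr) if k else
                                    np.empty((n_plain, 0)), expr], axis=1)
            rows.append(block)

    names += _gene_names("DIST", n_distractors)
    if n_distractors:
        block = np.empty((n_distractors, n_s))
        for j in range(n_distractors):
            if j % 2 == 0:
                # lapses: expressed at some stage, silent at a later one
                on = rng.integers(0, n_s - 1)
                off = rng.integers(on + 1, n_s)
                row = _silent(rng, n_s, thr)
                row[on:off] = _expressed(rng, off - on, thr)
                row[off] = rng.uniform(0.0, thr)
            else:
                row = _silent(rng, n_s, thr)  # never expressed
            block[j] = row
        rows.append(block)

    if len(set(names)) != len(names):
        raise ValueError("generated gene names collide")
    values = np.concatenate(rows, axis=0) if rows else np.empty((0, n_s))
    return pd.DataFrame(values, index=names, columns=stages)


def _silent_block(rng, shape, thr):  # pragma: no cover - tiny helper
    return rng.uniform(0.0, thr, size=shape)


# ---------------------------------------------------------------------------
# planted co-expression modules
# ---------------------------------------------------------------------------

def gen_module_expression(module_sizes: Sequence[int], n_samples: int,
                          latent_loading: float, cfg: SynthConfig,
                          baseline: float = 8.0
                          ) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression matrix with planted block-correlation modules.

    Gene ``g`` in module ``m`` is generated as
    ``baseline + loading * f_m + noise`` with one standard-normal latent
    factor ``f_m`` per module per sample and independent Gaussian noise of
    SD ``cfg.noise_sd``; the ``cfg.n_background`` background genes are unit
    pure noise around the baseline.  The baseline keeps values on a
    log2(FPKM+1)-like non-negative scale without affecting correlations.

    Returns the matrix and the planted labels (module 1..M, background 0).
    """
    module_sizes = [int(s) for s in module_sizes]
    if any(s < 1 for s in module_sizes):
        raise ValueError("module sizes must be >= 1")
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if not (0 < latent_loading <= 1):
        raise ValueError("latent_loading must be in (0, 1]")

    rng = cfg.rng("modules")
    names: list[str] = []
    labels: list[int] = []
    blocks: list[np.ndarray] = []
    for m, size in enumerate(module_sizes, start=1):
        f = rng.standard_normal(n_samples)
        noise = rng.standard_normal((size, n_samples)) * cfg.noise_sd
        blocks.append(latent_loading * f[None, :] + noise)
        names += _gene_names(f"MOD{m}G", size)
        labels += [m] * size
    if cfg.n_background:
        blocks.append(rng.standard_normal((cfg.n_background, n_samples)))
        names += _gene_names("BGG", cfg.n_background)
        labels += [0] * cfg.n_background
    if not blocks:
        raise ValueError("no genes requested (empty module list and no background)")
    values = np.concatenate(blocks, axis=0) + baseline
    values = np.clip(values, 0.0, None)  # stay on a non-negative expression scale
    samples = [f"SAMPLE{i:04d}" for i in range(1, n_samples + 1)]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=names, columns=samples), "log2fpkm1")
    return matrix, pd.Series(labels, index=names, name="module")


# ---------------------------------------------------------------------------
# scored interaction graph with planted hubs
# ---------------------------------------------------------------------------

def gen_interaction_graph(n_nodes: int, hub_spec: Mapping[str, int],
                          edge_score_range: tuple[float, float],
                          cfg: SynthConfig) -> nx.Graph:
    """Scored undirected interaction graph with planted high-degree hubs.

    Every hub named in ``hub_spec`` reaches exactly its target degree by
    attaching to non-hub nodes; non-hub degrees stay below 3, so a
    degree >= 3 hub caller recovers exactly the planted hubs.  Edge scores
    are sampled uniformly in ``edge_score_range``.
    """
    lo, hi = edge_score_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("edge_score_range must satisfy 0 <= lo <= hi <= 1")
    if n_nodes < 1:
        raise ValueError("need >= 1 node")
    hubs = list(hub_spec)
    if len(hubs) > n_nodes:
        raise ValueError("more hubs than nodes")
    for h, d in hub_spec.items():
        if d > n_nodes - 1:
            raise ValueError(f"target degree {d} for hub {h!r} exceeds n_nodes - 1")
        if d < 0:
            raise ValueError("target degrees must be >= 0")

    n_other = n_nodes - len(hubs)
    others = _gene_names("NODE", n_other)
    if set(others) & set(hubs):
        raise ValueError("hub names collide with generated node names")
    total_demand = sum(hub_spec.values())
    if total_demand > 2 * n_other:
        raise ValueError(
            f"infeasible degree sequence: hubs demand {total_demand} edge endpoints "
            f"but {n_other} non-hub nodes can absorb at most {2 * n_other}"
        )

    rng = cfg.rng("interactions")
    g = nx.Graph()
    g.add_nodes_from(hubs)
    g.add_nodes_from(others)
    stub_degree = {o: 0 for o in others}
    for h in hubs:
        # attach to the least-used non-hubs first so no non-hub exceeds degree 2
        avail = sorted((d, o) for o, d in stub_degree.items() if d < 2)
        need = hub_spec[h]
        if len(avail) < need:
            raise ValueError("infeasible degree sequence during attachment")
        for _, o in avail[:need]:
            g.add_edge(h, o, score=float(rng.uniform(lo, hi)))
            stub_degree[o] += 1
    # sprinkle a few edges between untouched non-hubs (degrees stay <= 2)
    free = [o for o, d in stub_degree.items() if d == 0]
    for a, b in zip(free[::2], free[1::2]):
        if rng.random() < 0.3:
            g.add_edge(a, b, score=float(rng.uniform(lo, hi)))
    return g


# ---------------------------------------------------------------------------
# DEG tables with planted reference overlap
# ---------------------------------------------------------------------------

def gen_deg_tables(reference: GeneSet, n_overlap_up: int, n_overlap_down: int,
                   n_extra: int, cfg: SynthConfig) -> pd.DataFrame:
    """DEG table overlapping a reference set in exactly the planted counts.

    The first ``n_overlap_up`` reference genes are marked up (fold >= 2,
    p < 0.05), the next ``n_overlap_down`` down, and ``n_extra`` non-reference
    genes are appended (alternating direction).  Every row passes the
    standard significance filter, so the table is invariant under it.
    """
    if n_overlap_up < 0 or n_overlap_down < 0 or n_extra < 0:
        raise ValueError("counts must be >= 0")
    if n_overlap_up + n_overlap_down > len(reference):
        raise ValueError("overlap exceeds reference size")
    rng = cfg.rng("deg")
    members = list(reference.members)
    up_genes = members[:n_overlap_up]
    down_genes = members[n_overlap_up:n_overlap_up + n_overlap_down]
    extra = _gene_names("EXTRA", n_extra)
    if set(extra) & set(members):
        raise ValueError("extra gene names collide with reference members")

    genes = up_genes + down_genes + extra
    n = len(genes)
    fc = np.empty(n)
    fc[:n_overlap_up] = rng.uniform(2.0, 8.0, size=n_overlap_up)
    fc[n_overlap_up:n_overlap_up + n_overlap_down] = -rng.uniform(2.0, 8.0, size=n_overlap_down)
    signs = np.where(np.arange(n_extra) % 2 == 0, 1.0, -1.0)
    fc[n_overlap_up + n_overlap_down:] = signs * rng.uniform(2.0, 8.0, size=n_extra)
    p = rng.uniform(1e-6, 0.049, size=n)
    return make_deg_table(genes, fc, p)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, **ground_truth) -> None:
    """Write a JSON ground-truth manifest alongside a generated fixture."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        if isinstance(o, GeneSet):
            return {"name": o.name, "members": list(o.members)}
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(ground_truth, indent=2, sort_keys=True, default=_default) + "\n")
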