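"""Reference gene-set derivation.

Covers the curation steps that turn annotation tables, ortholog maps, a
multi-tissue consensus expression atlas and stage-ordered differentiation
profiles into the reference sets used for maturity scoring:

* keyword mining of GO annotations for muscle-function genes,
* table-driven ortholog mapping,
* the tissue-restricted expression signature (expressed in the target
  tissue and nowhere else),
* stage-onset persistence classification over an ordered differentiation
  axis (pluripotent -> presomite -> myogenic progenitor -> myoblast ->
  myotube),
* "maintenance" genes whose expression rises monotonically toward the
  fully differentiated stage, and
* unique-upregulation set algebra across cell types.

"Expressed" consistently means a value strictly above ``expr_threshold``
(default 1.0), mirroring the NX > 1 convention of consensus tissue atlases.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "read_annotations",
    "read_gaf",
    "read_ortholog_map",
    "mine_go_annotations",
    "map_orthologs",
    "restricted_signature",
    "stage_onset_sets",
    "maintenance_genes",
    "unique_upregulated",
    "write_stage_table",
]

_GO_ID = re.compile(r"^GO:\d{7}$")
_ONTOLOGIES = {"BP", "CC", "MF"}
_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


# ---------------------------------------------------------------------------
# annotation and ortholog tables
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a TSV annotation table (gene_id, go_id, go_term, ontology)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_id", "go_id", "go_term", "ontology") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.loc[~df["go_id"].str.match(_GO_ID), "go_id"]
    if len(bad):
        raise ValueError(f"malformed GO id {bad.iloc[0]!r}")
    bad_ont = set(df["ontology"]) - _ONTOLOGIES
    if bad_ont:
        raise ValueError(f"unknown ontology code(s) {sorted(bad_ont)}")
    if df.duplicated().any():
        df = df.drop_duplicates(ignore_index=True)
    return df


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x file into the annotation-table layout.

    GAF carries no term text, so ``go_term`` is empty; such tables support
    gene <-> GO-id joins but not keyword mining.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"{path}: GAF line with {len(f)} columns")
        rows.append({"gene_id": f[2].strip(), "go_id": f[4].strip(),
                     "go_term": "", "ontology": _GAF_ASPECT.get(f[8].strip(), f[8].strip())})
    return validate_annotations(pd.DataFrame(rows, columns=["gene_id", "go_id", "go_term", "ontology"]))


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (source_gene, target_gene); empty/NA target = unmapped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (source, target)")
    df = df.iloc[:, :2]
    df.columns = ["source_gene", "target_gene"]
    df["target_gene"] = df["target_gene"].replace({"NA": "", "na": ""})
    if df["source_gene"].duplicated().any():
        dup = df.loc[df["source_gene"].duplicated(), "source_gene"].iloc[0]
        raise ValueError(f"duplicate source gene {dup!r} in ortholog map")
    return df


# ---------------------------------------------------------------------------
# GO keyword mining and ortholog mapping
# ---------------------------------------------------------------------------

def mine_go_annotations(table: pd.DataFrame, keywords: Sequence[str],
                        set_name: str = "go_keyword_genes") -> tuple[list[str], GeneSet]:
    """Select GO terms by case-insensitive substring match and collect their genes.

    A term matches if any keyword occurs verbatim (case-insensitively)
    inside its text — no stemming and no spelling variants, so e.g. the
    keyword "Z disk" does not match a term spelled "Z disc"; curating
    variants is the caller's responsibility.  Returns the matched GO ids
    (sorted) and the union of genes annotated to them.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kws = [k.lower() for k in keywords]
    terms = table["go_term"].fillna("").str.lower()
    hit = terms.apply(lambda t: any(k in t for k in kws))
    go_ids = sorted(set(table.loc[hit, "go_id"]))
    genes = table.loc[table["go_id"].isin(go_ids), "gene_id"]
    members = tuple(dict.fromkeys(genes))  # first-occurrence order, deduplicated
    return go_ids, GeneSet(set_name, f"genes of GO terms matching {len(keywords)} keywords", members)


def map_orthologs(genes: GeneSet, ortholog_map: pd.DataFrame,
                  set_name: str | None = None) -> tuple[GeneSet, list[str], list[str]]:
    """Map a gene set through a one-to-one ortholog table.

    Returns (mapped set, unmapped sources, log lines).  Sources absent from
    the table or mapped to an empty target are unmapped; two sources hitting
    the same target are collapsed to one member, which is noted in the log.
    Input order is preserved throughout.
    """
    lookup = dict(zip(ortholog_map["source_gene"], ortholog_map["target_gene"]))
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    log: list[str] = []
    for g in genes.members:
        target = lookup.get(g, "")
        if not target:
            unmapped.append(g)
            continue
        if target in mapped:
            log.append(f"collapse: {g} -> {target} (already mapped from {mapped[target]})")
            continue
        mapped[target] = g
    out = GeneSet(set_name or f"{genes.name}_orthologs",
                  f"orthologs of {genes.name}", tuple(mapped))
    return out, unmapped, log


# ---------------------------------------------------------------------------
# tissue-restricted signature
# ---------------------------------------------------------------------------

def restricted_signature(consensus: ExpressionMatrix, target_tissue: str,
                         expr_threshold: float = 1.0,
                         set_name: str = "restricted_signature") -> GeneSet:
    """Genes expressed in the target tissue and in no other tissue.

    A gene qualifies iff its value is strictly above ``expr_threshold`` in
    ``target_tissue`` and at or below the threshold in every other tissue
    of the consensus atlas.
    """
    if consensus.kind != "nx":
        raise ValueError(f"expected an NX consensus matrix, got {consensus.kind!r}")
    if target_tissue not in consensus.sample_ids:
        raise ValueError(f"target tissue {target_tissue!r} not in matrix")
    vals = consensus.values
    in_target = vals[target_tissue] > expr_threshold
    others = vals.drop(columns=[target_tissue])
    elsewhere = (others > expr_threshold).any(axis=1) if others.shape[1] else \
        pd.Series(False, index=vals.index)
    members = tuple(vals.index[in_target & ~elsewhere])
    return GeneSet(set_name, f"expressed only in {target_tissue}", members)


# ---------------------------------------------------------------------------
# stage-onset persistence and maintenance
# ---------------------------------------------------------------------------

def _validate_profiles(profiles: pd.DataFrame) -> None:
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 ordered stages")
    if profiles.columns.duplicated().any():
        raise ValueError("duplicate stage names")
    if (profiles.to_numpy() < 0).any():
        raise ValueError("stage means must be >= 0")


def stage_onset_sets(profiles: pd.DataFrame, expr_threshold: float = 1.0
                     ) -> dict[str, GeneSet]:
    """Partition genes by the differentiation stage at which expression starts.

    A gene has onset at stage ``k`` iff it is at or below the threshold at
    every stage before ``k`` and strictly above it at ``k`` and every later
    stage.  Genes that are never expressed, or whose expression lapses after
    onset, have no onset and are excluded.  The per-stage sets are pairwise
    disjoint by construction.
    """
    _validate_profiles(profiles)
    stages = list(profiles.columns)
    expressed = profiles.to_numpy() > expr_threshold
    out: dict[str, GeneSet] = {}
    claimed = np.zeros(len(profiles), dtype=bool)
    for k, stage in enumerate(stages):
        silent_before = ~expressed[:, :k].any(axis=1) if k else np.ones(len(profiles), bool)
        persistent_from = expressed[:, k:].all(axis=1)
        mask = silent_before & persistent_from & ~claimed
        claimed |= mask
        out[stage] = GeneSet(f"onset_{stage}", f"persistently expressed from stage {stage}",
                             tuple(profiles.index[mask]))
    return out


def maintenance_genes(profiles: pd.DataFrame, expr_threshold: float = 1.0,
                      min_rel_increase: float = 0.0,
                      set_name: str = "maintenance_genes"
                      ) -> tuple[GeneSet, dict[str, int]]:
    """Stage-onset genes whose expression rises strictly toward the final stage.

    Among the stage-onset persistent genes, keeps those whose stage means
    increase strictly from onset to the final stage (each step must exceed
    ``min_rel_increase`` times the previous value).  A gene needs at least
    one increasing step, so final-stage-onset genes never qualify.  Returns
    the set and its per-onset-stage breakdown.
    """
    onset_sets = stage_onset_sets(profiles, expr_threshold)
    stages = list(profiles.columns)
    members: list[str] = []
    breakdown = {stage: 0 for stage in stages}
    for k, stage in enumerate(stages[:-1]):
        for g in onset_sets[stage].members:
            vals = profiles.loc[g].to_numpy()[k:]
            steps_ok = all(b - a > min_rel_increase * a for a, b in zip(vals[:-1], vals[1:]))
            if steps_ok:
                members.append(g)
                breakdown[stage] += 1
    gene_set = GeneSet(set_name, "monotonically increasing toward the differentiated stage",
                       tuple(members))
    return gene_set, breakdown


# ---------------------------------------------------------------------------
# unique upregulation
# ---------------------------------------------------------------------------

def unique_upregulated(sets: Mapping[str, GeneSet], candidates: GeneSet
                       ) -> dict[str, GeneSet]:
    """Per label: candidate genes present in that label's set and in no other.

    ``(set_l ∩ candidates) \\ ∪_{m != l} set_m`` for every label ``l``.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 labelled sets")
    cand = candidates.as_set()
    out: dict[str, GeneSet] = {}
    for label, gs in sets.items():
        others = set().union(*(o.as_set() for lab, o in sets.items() if lab != label))
        members = tuple(g for g in gs.members if g in cand and g not in others)
        out[label] = GeneSet(f"unique_up_{label}", f"candidates unique to {label}", members)
    return out


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_stage_table(profiles: pd.DataFrame, onset_sets: Mapping[str, GeneSet],
                      maintenance: GeneSet, path: str | Path) -> None:
    """Per-gene TSV: gene, onset_stage (empty if none), maintenance_flag."""
    onset_of = {g: stage for stage, gs in onset_sets.items() for g in gs.members}
    maint = maintenance.as_set()
    with Path(path).open("w") as fh:
        fh.write("gene_id\tonset_stage\tmaintenance_flag\n")
        for g in profiles.index:
            fh.write(f"{g}\t{onset_of.get(g, '')}\t{int(g in maint)}\n")
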