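"""Maturity scoring of reprogrammed-cell transcriptomes against reference sets.

Given per-cell-type differential-expression tables and the reference
objects derived elsewhere in the package (core-GRN hub set, tissue-restricted
signature, stage-onset sets, maintenance genes), this module computes the
per-cell-type maturity report: overlap counts and percentages with the hub
network, stage composition of the upregulated transcripts, signature
coverage and maintenance-gene coverage, plus the up/down intersections
common to all cell types.

Percentages are rounded half-away-from-zero (to 2 decimals by default),
the convention that reproduces printed figures such as 42/116 = 36.21%.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import genesets
from .io import (GeneSet, deg_direction_sets, filter_deg, read_deg, read_gene_list,
                 read_gmt)

__all__ = [
    "CommonDEG",
    "round_half_away",
    "common_degs",
    "overlap_stats",
    "stage_composition",
    "signature_coverage",
    "maintenance_coverage",
    "build_report",
    "write_report",
]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (2.345 -> 2.35, -2.345 -> -2.35)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(str(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


def _pct(count: int, total: int, decimals: int) -> float:
    # exact rational percentage, then half-away-from-zero rounding
    q = Decimal(1).scaleb(-decimals)
    d = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass
class CommonDEG:
    """Up/down gene sets shared by every cell type, with direction conflicts logged."""

    up: set[str]
    down: set[str]
    conflicts: set[str]


def common_degs(tables: Mapping[str, pd.DataFrame]) -> CommonDEG:
    """Intersect filtered DEG tables across cell types.

    ``up`` is the intersection of the per-cell-type up sets, ``down`` of the
    down sets.  Genes called up in one cell type and down in another cannot
    be common to either direction; they are reported in ``conflicts``.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 DEG tables to intersect")
    ups, downs = [], []
    for label, t in tables.items():
        up, down = deg_direction_sets(t)
        ups.append(up)
        downs.append(down)
    any_up = set().union(*ups)
    any_down = set().union(*downs)
    conflicts = any_up & any_down
    common_up = set.intersection(*ups) - conflicts
    common_down = set.intersection(*downs) - conflicts
    return CommonDEG(up=common_up, down=common_down, conflicts=conflicts)


def overlap_stats(up: set[str] | GeneSet, down: set[str] | GeneSet, reference: GeneSet,
                  pct_decimals: int = 2) -> dict:
    """Overlap counts and percentages of up/down sets with a reference set."""
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    ref = reference.as_set()
    up = set(up)
    down = set(down)
    n_up, n_down = len(up & ref), len(down & ref)
    return {
        "up_count": n_up,
        "down_count": n_down,
        "reference_size": len(ref),
        "up_pct": _pct(n_up, len(ref), pct_decimals),
        "down_pct": _pct(n_down, len(ref), pct_decimals),
    }


def stage_composition(up: set[str] | GeneSet, stage_sets: Mapping[str, GeneSet],
                      pct_decimals: int = 2) -> dict[str, dict]:
    """Per-stage overlap of upregulated genes with each stage-onset set.

    The percentage is relative to the stage set's own size.  An empty stage
    set is reported with count 0 and percentage ``None`` (undefined).
    Raises if the stage sets are not pairwise disjoint.
    """
    seen: set[str] = set()
    for gs in stage_sets.values():
        if seen & gs.as_set():
            raise ValueError("stage sets must be pairwise disjoint")
        seen |= gs.as_set()
    up = set(up)
    out = {}
    for stage, gs in stage_sets.items():
        n = len(up & gs.as_set())
        out[stage] = {
            "count": n,
            "stage_set_size": len(gs),
            "pct": _pct(n, len(gs), pct_decimals) if len(gs) else None,
        }
    return out


def signature_coverage(expressed_or_up: set[str] | GeneSet, signature: GeneSet) -> int:
    """Number of signature genes present in the given gene set."""
    return len(set(expressed_or_up) & signature.as_set())


def maintenance_coverage(reference_transcriptome: set[str] | GeneSet, maintenance: GeneSet,
                         pct_decimals: int = 0) -> tuple[int, float]:
    """Count and percentage of maintenance genes present in a transcriptome."""
    if len(maintenance) == 0:
        raise ValueError("maintenance set must be non-empty")
    count = len(set(reference_transcriptome) & maintenance.as_set())
    return count, _pct(count, len(maintenance), pct_decimals)


# ---------------------------------------------------------------------------
# report orchestration
# ---------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _single_gmt(path: str | Path) -> GeneSet:
    sets = read_gmt(path)
    if len(sets) != 1:
        raise ValueError(f"{path}: expected exactly one gene set, found {len(sets)}")
    return sets[0]


def build_report(config: Mapping) -> dict:
    """Run the full scoring workflow from a configuration mapping.

    Expected layout (paths under ``inputs`` are read from disk)::

        inputs:
          deg_tables: {label: path, ...}     # required
          fold_scale: linear | log2          # default linear
          grn: path.gmt                      # hub reference (optional)
          signature: path.gmt                # restricted signature (optional)
          stage_sets: path.gmt               # one set per stage, file order = stage order
          maintenance: path.gmt              # maintenance genes (optional)
          reference_transcriptome: path      # one gene per line (optional)
          expressed: {label: path}           # per-cell-type expressed genes (optional;
                                             # defaults to the up-regulated DEGs)
        thresholds: {p_max: 0.05, min_fold: 2.0}
        scoring: {pct_decimals: 2, maintenance_pct_decimals: 0}

    Missing optional references simply omit the corresponding report
    sections.  The report records every threshold and an SHA-256 hash of
    every input file, so a rerun on identical inputs is byte-identical.
    """
    inputs = config.get("inputs", {})
    thresholds = config.get("thresholds", {})
    scoring_cfg = config.get("scoring", {})
    p_max = float(thresholds.get("p_max", 0.05))
    min_fold = float(thresholds.get("min_fold", 2.0))
    pct_decimals = int(scoring_cfg.get("pct_decimals", 2))
    maint_decimals = int(scoring_cfg.get("maintenance_pct_decimals", 0))
    fold_scale = inputs.get("fold_scale", "linear")

    deg_paths = inputs.get("deg_tables")
    if not deg_paths:
        raise ValueError("missing config key inputs.deg_tables")
    hashes = {}
    tables: dict[str, pd.DataFrame] = {}
    for label, path in deg_paths.items():
        if not Path(path).exists():
            raise ValueError(f"inputs.deg_tables[{label!r}]: file not found: {path}")
        hashes[f"deg_tables.{label}"] = _sha256(path)
        tables[label] = filter_deg(read_deg(path, fold_scale), p_max, min_fold)

    refs: dict[str, object] = {}
    for key, loader in (("grn", _single_gmt), ("signature", _single_gmt),
                        ("maintenance", _single_gmt)):
        if inputs.get(key):
            if not Path(inputs[key]).exists():
                raise ValueError(f"inputs.{key}: file not found: {inputs[key]}")
            refs[key] = loader(inputs[key])
            hashes[key] = _sha256(inputs[key])
    stage_sets: dict[str, GeneSet] | None = None
    if inputs.get("stage_sets"):
        hashes["stage_sets"] = _sha256(inputs["stage_sets"])
        stage_sets = {gs.name: gs for gs in read_gmt(inputs["stage_sets"])}
    reference_transcriptome = None
    if inputs.get("reference_transcriptome"):
        hashes["reference_transcriptome"] = _sha256(inputs["reference_transcriptome"])
        reference_transcriptome = set(read_gene_list(inputs["reference_transcriptome"]))
    expressed: dict[str, set[str]] = {}
    for label, path in (inputs.get("expressed") or {}).items():
        hashes[f"expressed.{label}"] = _sha256(path)
        expressed[label] = set(read_gene_list(path))

    report: dict = {
        "parameters": {"p_max": p_max, "min_fold": min_fold, "fold_scale": fold_scale,
                       "pct_decimals": pct_decimals,
                       "maintenance_pct_decimals": maint_decimals},
        "input_hashes": hashes,
        "cell_types": {},
    }

    for label, table in tables.items():
        up, down = deg_direction_sets(table)
        entry: dict = {"n_up": len(up), "n_down": len(down)}
        if "grn" in refs:
            entry["grn"] = overlap_stats(up, down, refs["grn"], pct_decimals)
        if stage_sets is not None:
            entry["stage_composition"] = stage_composition(up, stage_sets, pct_decimals)
        if "signature" in refs:
            exp_set = expressed.get(label, up)
            entry["signature_expressed_count"] = signature_coverage(exp_set, refs["signature"])
        if "maintenance" in refs:
            exp_set = expressed.get(label, up)
            count, pct = maintenance_coverage(exp_set, refs["maintenance"], maint_decimals)
            entry["maintenance_expressed_count"] = count
            entry["maintenance_pct"] = pct
        report["cell_types"][label] = entry

    if len(tables) >= 2:
        common = common_degs(tables)
        section: dict = {"up_count": len(common.up), "down_count": len(common.down),
                         "conflicts": sorted(common.conflicts)}
        if "grn" in refs:
            section["grn"] = overlap_stats(common.up, common.down, refs["grn"], pct_decimals)
        report["common"] = section

    if "maintenance" in refs and reference_transcriptome is not None:
        count, pct = maintenance_coverage(reference_transcriptome, refs["maintenance"],
                                          maint_decimals)
        report["maintenance_in_reference"] = {"count": count, "pct": pct,
                                              "maintenance_size": len(refs["maintenance"])}
    return report


def write_report(report: dict, json_path: str | Path | None = None,
                 tsv_path: str | Path | None = None) -> None:
    """Emit the report as canonical JSON and/or a flat (cell_type, metric, value) TSV."""
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        rows = []

        def _flatten(prefix: str, obj, cell_type: str) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    _flatten(f"{prefix}.{k}" if prefix else str(k), v, cell_type)
            elif isinstance(obj, list):
                rows.append((cell_type, prefix, ";".join(map(str, obj))))
            else:
                rows.append((cell_type, prefix, obj))

        for ct, entry in report.get("cell_types", {}).items():
            _flatten("", entry, ct)
        for key in ("common", "maintenance_in_reference"):
            if key in report:
                _flatten(key, report[key], "-")
        with Path(tsv_path).open("w") as fh:
            fh.write("cell_type\tmetric\tvalue\n")
            for ct, metric, value in rows:
                fh.write(f"{ct}\t{metric}\t{value}\n")
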