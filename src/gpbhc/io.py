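"""Readers and writers for the tool's on-disk formats.

Expression tables are tab-delimited: first column the gene id, remaining
columns named ``<timeLabel>_r<k>`` for replicate ``k`` of a time point.
A YAML/JSON sidecar maps each time label to its numeric time, so
non-uniform or non-numeric labels stay unambiguous.  Outputs of a run are
a label-only Newick dendrogram, a partition TSV, a scores TSV, and a JSON
run report with the configuration, noise prior, fitted hyperparameters
and merge trace.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bhc import ClusterNode, Dendrogram
from .config import RunConfig
from .dataset import DatasetError, TimeSeriesDataset
from .metrics import PartitionScore
from .preprocess import NoisePrior

logger = logging.getLogger(__name__)

_COLUMN_RE = re.compile(r"^(?P<label>.+)_r(?P<rep>\d+)$")


class ParseError(ValueError):
    """Raised for malformed input tables or sidecars."""


def read_sidecar(path: str | Path) -> dict[str, float]:
    """Time-label -> numeric-time mapping from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ParseError(f"sidecar {path} must map time labels to numeric times")
    return {str(k): float(v) for k, v in data.items()}


def read_expression_table(
    path: str | Path, sidecar: str | Path | dict[str, float]
) -> TimeSeriesDataset:
    """Load a replicated expression table into a dataset.

    Columns are grouped by time label, ordered by numeric time (reordering
    is logged), and stacked into the (replicate, gene, time) array with
    NaN padding for time points that have fewer replicates.
    """
    times_map = sidecar if isinstance(sidecar, dict) else read_sidecar(sidecar)
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene-id column plus data columns")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    dup = df[gene_col][df[gene_col].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    if df.isna().any().any():
        row = int(np.where(df.isna().any(axis=1))[0][0]) + 2  # 1-based + header
        raise ParseError(f"{path}: ragged/missing value at line {row}")

    by_label: dict[str, dict[int, str]] = {}
    for col in df.columns[1:]:
        m = _COLUMN_RE.match(col)
        if not m:
            raise ParseError(
                f"{path}: column {col!r} does not match '<timeLabel>_r<k>'"
            )
        label, rep = m.group("label"), int(m.group("rep"))
        if label not in times_map:
            raise ParseError(
                f"{path}: time label {label!r} missing from the sidecar"
            )
        by_label.setdefault(label, {})
        if rep in by_label[label]:
            raise ParseError(f"{path}: duplicate column {col!r}")
        by_label[label][rep] = col

    ordered = sorted(by_label, key=lambda lb: times_map[lb])
    if ordered != [lb for lb in df.columns[1:].map(
            lambda c: _COLUMN_RE.match(c).group("label")).unique()]:
        logger.info("columns reordered by numeric time")
    times = np.array([times_map[lb] for lb in ordered])
    G, T = len(gene_ids), len(ordered)
    R = max(len(cols) for cols in by_label.values())
    raw = np.full((R, G, T), np.nan)
    for t, lb in enumerate(ordered):
        for slot, rep in enumerate(sorted(by_label[lb])):
            raw[slot, :, t] = df[by_label[lb][rep]].to_numpy(dtype=float)
    try:
        return TimeSeriesDataset(gene_ids=gene_ids, times=times, raw=raw)
    except DatasetError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression_table(
    dataset: TimeSeriesDataset, path: str | Path, sidecar_path: str | Path
) -> None:
    """Write a dataset back to the TSV + sidecar format (round-trippable)."""
    cols: dict[str, np.ndarray] = {}
    sidecar: dict[str, float] = {}
    for t in range(dataset.T):
        label = f"t{t}"
        sidecar[label] = float(dataset.times[t])
        for r in range(dataset.R):
            col = dataset.raw[r, :, t]
            if np.isnan(col).all():
                continue
            cols[f"{label}_r{r + 1}"] = col
    df = pd.DataFrame({"gene_id": dataset.gene_ids, **cols})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    Path(sidecar_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, semicolon-joined terms) -> term-set mapping."""
    out: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {ln}: expected two tab-separated fields")
        gene, terms = parts
        out[gene] = {t for t in terms.split(";") if t}
    return out


def _params_record(node: ClusterNode) -> dict:
    p = node.params
    rec = {"kind": p.kind, "signal_var": p.signal_var, "noise_var": p.noise_var,
           "a": node.a}
    if p.length_scale is not None:
        rec["length_scale"] = p.length_scale
    return rec


def write_outputs(
    dend: Dendrogram,
    partition: pd.DataFrame,
    scores: list[PartitionScore],
    config: RunConfig,
    outdir: str | Path,
    prior: NoisePrior | None = None,
    dataset: TimeSeriesDataset | None = None,
) -> dict[str, Path]:
    """Write Newick tree, partition TSV, scores TSV and the JSON run report.

    With ``dataset`` given, the normalized averaged profiles are also
    written (one row per gene, one column per time point).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "newick": outdir / "dendrogram.nwk",
        "partition": outdir / "partition.tsv",
        "scores": outdir / "scores.tsv",
        "report": outdir / "run_report.json",
    }
    if dataset is not None and dataset.profiles is not None:
        paths["profiles"] = outdir / "profiles.tsv"
        prof = pd.DataFrame(
            dataset.profiles, index=pd.Index(dataset.gene_ids, name="gene_id"),
            columns=[f"{t:g}" for t in dataset.times],
        )
        prof.to_csv(paths["profiles"], sep="\t", float_format="%.10g")
    paths["newick"].write_text(dend.to_newick() + "\n")
    partition.to_csv(paths["partition"], sep="\t", index=False,
                     float_format="%.6g")
    score_df = pd.DataFrame(
        [{"statistic": s.name, "value": s.value, "stderr": s.stderr,
          "n_boot": s.n_boot, "seed": s.seed} for s in scores]
    )
    score_df.to_csv(paths["scores"], sep="\t", index=False, float_format="%.6g")

    cluster_nodes = {}
    for cid, sub in partition.groupby("cluster_id"):
        members = set(sub["gene_id"])
        node = _find_node(dend.root, members, dend.gene_ids)
        cluster_nodes[str(cid)] = {
            "genes": sorted(members), "r": node.r, **_params_record(node),
        }
    report = {
        "config": config.to_dict(),
        "crp_alpha": dend.crp_alpha,
        "kernel": dend.kernel,
        "root_log_tree": dend.root_log_tree,
        "noise_prior": None if prior is None else asdict(prior),
        "clusters": cluster_nodes,
        "merge_trace": dend.merge_trace,
    }
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True,
                                          default=float) + "\n")
    return paths


def _find_node(root: ClusterNode, members: set[str], gene_ids: list[str]) -> ClusterNode:
    node_members = {gene_ids[g] for g in root.members}
    if node_members == members:
        return root
    if root.is_leaf or not members <= node_members:
        raise ValueError("cluster members do not correspond to a tree node")
    left, right = root.children
    left_members = {gene_ids[g] for g in left.members}
    return _find_node(left if members <= left_members else right,
                      members, gene_ids)
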