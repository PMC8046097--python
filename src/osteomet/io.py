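"""Readers and writers for the on-disk fixture formats.

All files are UTF-8, tab-separated, decimal point:

* ``intensities.tsv`` — first column ``metabolite``, one column per sample;
  missing cells are empty fields;
* ``samples.tsv`` — one row per sample with the metadata columns of the
  study layout (RCT or cohort);
* ``annotations.tsv`` — metabolite, name, class, sub_pathway;
* ``truth.json`` — planted ground truth of a synthetic dataset;
* pathway files — GMT-style: ``pathway_id TAB name TAB member TAB member``
  per line, plus optional per-pathway edge lists
  (``<pathway_id>.edges.tsv``: two member ids per line) for topology
  impact.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (GroundTruth, IntensityMatrix, validate_cohort_samples,
                         validate_rct_samples)
from .enrichment import PathwaySet

__all__ = ["read_matrix", "read_samples", "read_annotations", "read_truth",
           "read_pathways", "write_pathways"]


def read_matrix(path: str | Path, stage: str = "raw") -> IntensityMatrix:
    """Read an intensity matrix; empty cells become missing values."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "metabolite":
        raise ValueError(f"{path}: first column must be 'metabolite', got "
                         f"{header[0] if header else 'nothing'!r}")
    seen = set()
    for col in header[1:]:
        if col in seen:
            raise ValueError(f"{path}: duplicated sample column {col!r}")
        seen.add(col)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse intensity table ({exc})")
    data = raw.set_index("metabolite")
    data.index.name = None
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated metabolite id {dup!r}")
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric intensity cell ({exc})")
    return IntensityMatrix(data, stage=stage)


def read_samples(path: str | Path, layout: str = "rct") -> pd.DataFrame:
    """Read and validate a sample metadata table (layout 'rct' or 'cohort')."""
    path = Path(path)
    samples = pd.read_csv(path, sep="\t")
    try:
        if layout == "rct":
            return validate_rct_samples(samples)
        if layout == "cohort":
            return validate_cohort_samples(samples)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}")
    raise ValueError(f"unknown sample layout {layout!r}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    ann = pd.read_csv(path, sep="\t")
    if "metabolite" not in ann.columns:
        raise ValueError(f"{path}: annotation table needs a 'metabolite' "
                         "column")
    if ann["metabolite"].duplicated().any():
        dup = ann.loc[ann["metabolite"].duplicated(), "metabolite"].iloc[0]
        raise ValueError(f"{path}: duplicated metabolite id {dup!r}")
    return ann


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def read_pathways(path: str | Path, edges_dir: str | Path | None = None
                  ) -> list[PathwaySet]:
    """Read a GMT-style pathway membership file (+ optional edge lists)."""
    path = Path(path)
    pathways = []
    seen = set()
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: expected at least 3 tab-separated "
                             "fields (id, name, members...)")
        pid, name, *members = fields
        if pid in seen:
            raise ValueError(f"{path}:{ln}: duplicate pathway id {pid!r}")
        seen.add(pid)
        members = [m for m in members if m]
        if len(set(members)) < len(members):
            raise ValueError(f"{path}:{ln}: duplicate members in {pid!r}")
        graph = None
        if edges_dir is not None:
            edge_path = Path(edges_dir) / f"{pid}.edges.tsv"
            if edge_path.exists():
                graph = nx.Graph()
                graph.add_nodes_from(members)
                for eln, eline in enumerate(edge_path.read_text()
                                            .splitlines(), start=1):
                    if not eline.strip():
                        continue
                    parts = eline.split("\t")
                    if len(parts) != 2:
                        raise ValueError(f"{edge_path}:{eln}: expected two "
                                         "tab-separated node ids")
                    graph.add_edge(*parts)
        pathways.append(PathwaySet(id=pid, name=name, members=members,
                                   graph=graph))
    if not pathways:
        raise ValueError(f"{path}: no pathways found")
    return pathways


def write_pathways(pathways, path: str | Path,
                   edges_dir: str | Path | None = None) -> None:
    path = Path(path)
    lines = []
    for pw in pathways:
        lines.append("\t".join([pw.id, pw.name, *sorted(pw.members)]))
        if edges_dir is not None and pw.graph is not None:
            edir = Path(edges_dir)
            edir.mkdir(parents=True, exist_ok=True)
            with open(edir / f"{pw.id}.edges.tsv", "w") as fh:
                for a, b in sorted(map(sorted, pw.graph.edges())):
                    fh.write(f"{a}\t{b}\n")
    path.write_text("\n".join(lines) + "\n")
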