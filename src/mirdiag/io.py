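"""Plain-text formats: probe-level TSV, annotation TSV, expression-matrix
TSV (the GEO series-matrix table dialect), ground-truth JSON, and a reader
for GEO series-matrix files.

All writers are paired with readers that accept their output losslessly.
Matrix files carry miRNAs in rows and samples in columns, tab-delimited
with a header row of sample ids — the layout a GEO series-matrix table
uses, so real deposited data and simulated fixtures share one dialect.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProbeLevelData, SampleAnnotation

__all__ = [
    "read_probe_tsv", "write_probe_tsv",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_ground_truth_json", "write_ground_truth_json",
    "read_expression_tsv", "write_expression_tsv",
    "read_geo_series_matrix",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


# --- probe-level long-format TSV -----------------------------------------

def write_probe_tsv(data: ProbeLevelData, path: str | Path) -> None:
    """Long format: columns array_id, mirna_id, replicate_index, intensity."""
    n_a, n_m, n_r = data.intensities.shape
    frame = pd.DataFrame({
        "array_id": np.repeat(data.array_ids, n_m * n_r),
        "mirna_id": np.tile(np.repeat(data.mirna_ids, n_r), n_a),
        "replicate_index": np.tile(np.arange(n_r), n_a * n_m),
        "intensity": data.intensities.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_probe_tsv(path: str | Path) -> ProbeLevelData:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"array_id", "mirna_id", "replicate_index", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"probe TSV must have columns {sorted(required)}")
    array_ids = list(dict.fromkeys(frame["array_id"].astype(str)))
    mirna_ids = list(dict.fromkeys(frame["mirna_id"].astype(str)))
    n_r = int(frame["replicate_index"].max()) + 1
    counts = frame.groupby(["array_id", "mirna_id"], sort=False).size()
    if (counts != n_r).any():
        bad = counts[counts != n_r].index[0]
        raise ValueError(f"inconsistent replicate count for {bad}")
    a_pos = {a: i for i, a in enumerate(array_ids)}
    m_pos = {m: i for i, m in enumerate(mirna_ids)}
    cube = np.full((len(array_ids), len(mirna_ids), n_r), np.nan)
    cube[frame["array_id"].astype(str).map(a_pos),
         frame["mirna_id"].astype(str).map(m_pos),
         frame["replicate_index"].to_numpy()] = frame["intensity"].to_numpy()
    if np.isnan(cube).any():
        raise ValueError("missing replicate entries in probe TSV")
    return ProbeLevelData(array_ids, mirna_ids, cube)


# --- sample annotation TSV ------------------------------------------------

def write_annotation_tsv(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> SampleAnnotation:
    tbl = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleAnnotation(tbl)


# --- ground-truth JSON ----------------------------------------------------

def write_ground_truth_json(truth, path: str | Path) -> None:
    payload = {
        "differential_sets": {k: sorted(v)
                              for k, v in truth.differential_sets.items()},
        "true_effects": [{"mirna_id": m, "class": c, "shift": s}
                         for (m, c), s in sorted(truth.true_effects.items())],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth_json(path: str | Path):
    from .synthetic import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        {k: set(v) for k, v in payload["differential_sets"].items()},
        {(e["mirna_id"], e["class"]): e["shift"]
         for e in payload["true_effects"]},
    )


# --- expression-matrix TSV ------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """miRNAs in rows, samples in columns; stage recorded in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# stage: {matrix.stage}\n")
        matrix.data.T.rename_axis("mirna_id").to_csv(
            fh, sep="\t", float_format=_FLOAT_FMT)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    stage = "raw-summarized"
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and lines[0].startswith("# stage:"):
        stage = lines[0].split(":", 1)[1].strip()
        lines = lines[1:]
    if not lines:
        raise ValueError("empty expression file")
    header = lines[0].split("\t")
    n_cols = len(header)
    sample_ids = header[1:]
    mirna_ids, values = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(f"line {lineno}: expected {n_cols} fields, "
                             f"got {len(fields)}")
        mirna_ids.append(fields[0])
        values.append([float(v) for v in fields[1:]])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    if len(set(mirna_ids)) != len(mirna_ids):
        raise ValueError("duplicate miRNA ids")
    frame = pd.DataFrame(np.asarray(values, dtype=float).T,
                         index=pd.Index(sample_ids, name="sample_id"),
                         columns=mirna_ids)
    return ExpressionMatrix(frame, stage=stage)


# --- GEO series-matrix reader ---------------------------------------------

_DEFAULT_CLASS_PATTERN = r"(?:diagnosis|disease state|class|status)\s*:\s*(.+)"


def read_geo_series_matrix(
    path: str | Path,
    class_pattern: str = _DEFAULT_CLASS_PATTERN,
    cohort: str = "unknown",
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Parse a GEO series-matrix file (plain-text dialect).

    Metadata lines start with ``!``; the expression table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` and is
    tab-delimited with double-quoted identifiers.  Class labels are pulled
    from ``!Sample_characteristics_ch1`` lines via ``class_pattern``
    (first capture group); samples without a match get class ``"unknown"``.
    """
    lines = Path(path).read_text().splitlines()
    meta: list[tuple[str, list[str]]] = []
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
        elif line.startswith("!"):
            key, *vals = line.split("\t")
            meta.append((key.lstrip("!"),
                         [v.strip().strip('"') for v in vals]))
    if begin is None or end is None or end <= begin:
        raise ValueError("series-matrix table fence missing or malformed")

    table_lines = lines[begin + 1:end]
    header = [f.strip().strip('"') for f in table_lines[0].split("\t")]
    sample_ids = header[1:]
    mirna_ids, values = [], []
    for lineno, line in enumerate(table_lines[1:], start=begin + 3):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"line {lineno}: ragged table row")
        mirna_ids.append(fields[0].strip().strip('"'))
        values.append([float(v) for v in fields[1:]])
    frame = pd.DataFrame(np.asarray(values, dtype=float).T,
                         index=pd.Index(sample_ids, name="sample_id"),
                         columns=mirna_ids)
    # deposited series matrices are already normalized
    matrix = ExpressionMatrix(frame, stage="normalized")

    classes = ["unknown"] * len(sample_ids)
    rx = re.compile(class_pattern, flags=re.IGNORECASE)
    for key, vals in meta:
        if key.lower() == "sample_characteristics_ch1":
            for j, v in enumerate(vals[:len(sample_ids)]):
                m = rx.search(v)
                if m:
                    classes[j] = m.group(1).strip()
    annotation = SampleAnnotation.from_labels(sample_ids, classes,
                                              cohort=cohort)
    return matrix, annotation
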