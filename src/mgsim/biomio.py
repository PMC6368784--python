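"""Minimal BIOM 1.0 (JSON dialect) reading and writing.

Only the subset needed for taxonomic input profiles is supported: an
observation (taxon) x sample table with a dense or sparse matrix.
Observation ids are free-text taxon names or taxon ids; abundances are
summed over samples (or taken from one named sample column) to yield the
(name, abundance) rows of an input profile.
"""

from __future__ import annotations

import json
from pathlib import Path


def read_biom_profile(path: str | Path, sample: str | None = None) -> list[tuple[str, float]]:
    """Read observation abundances from a BIOM 1.0 JSON table.

    Returns (observation id, abundance) rows, summing over all sample
    columns unless ``sample`` names one column id. Dense and sparse
    matrix encodings of the same table yield identical rows.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    try:
        rows = doc["rows"]
        cols = doc["columns"]
        shape = doc["shape"]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing BIOM key {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: BIOM table has no observations")
    n_obs, n_samp = int(shape[0]), int(shape[1])
    if len(rows) != n_obs or len(cols) != n_samp:
        raise ValueError(f"{path}: shape {shape} inconsistent with rows/columns")
    if sample is None:
        keep = list(range(n_samp))
    else:
        ids = [c["id"] for c in cols]
        if sample not in ids:
            raise ValueError(f"{path}: no sample column {sample!r} (have {ids})")
        keep = [ids.index(sample)]
    sums = [0.0] * n_obs
    if matrix_type == "dense":
        for i, rowvals in enumerate(data):
            for j in keep:
                sums[i] += float(rowvals[j])
    elif matrix_type == "sparse":
        keepset = set(keep)
        for i, j, v in data:
            if int(j) in keepset:
                sums[int(i)] += float(v)
    else:
        raise ValueError(f"{path}: unsupported matrix_type {matrix_type!r}")
    out = []
    for row, s in zip(rows, sums):
        if s < 0:
            raise ValueError(f"{path}: negative abundance for observation {row['id']!r}")
        out.append((str(row["id"]), s))
    return out


def write_biom(
    path: str | Path,
    observations: list[str],
    samples: list[str],
    matrix: list[list[float]],
    matrix_type: str = "dense",
    generated_by: str = "mgsim",
) -> None:
    """Write a BIOM 1.0 JSON table (dense or sparse encoding)."""
    if matrix_type == "dense":
        data = [[float(v) for v in row] for row in matrix]
    elif matrix_type == "sparse":
        data = [
            [i, j, float(v)]
            for i, row in enumerate(matrix)
            for j, v in enumerate(row)
            if v != 0
        ]
    else:
        raise ValueError(f"unsupported matrix_type {matrix_type!r}")
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": "1970-01-01T00:00:00",
        "rows": [{"id": o, "metadata": None} for o in observations],
        "columns": [{"id": s, "metadata": None} for s in samples],
        "matrix_type": matrix_type,
        "matrix_element_type": "float",
        "shape": [len(observations), len(samples)],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
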