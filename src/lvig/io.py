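"""Readers and writers for systems (A, b) and catalogs.

Two on-disk representations:

- headerless delimited text (CSV/TSV), one row per species, with an
  optional companion file for the growth-rate vector;
- a single JSON document ``{"A": [[...]], "b": [...], "labels": [...]}``.

Growth rates default to all ones when absent; species labels default to
``"1".."N"`` (1-based).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from lvig.matrices import as_growth_rates, as_interaction_matrix

__all__ = [
    "read_matrix",
    "read_vector",
    "read_system",
    "write_matrix",
    "write_system_json",
    "catalog_to_json",
]


def _sniff_delimiter(text: str) -> str:
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    return "\t" if "\t" in first else ","


def read_matrix(path) -> np.ndarray:
    """Read a headerless CSV/TSV matrix (delimiter sniffed per file)."""
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    try:
        rows = [
            [float(x) for x in ln.split(delim)]
            for ln in text.splitlines()
            if ln.strip()
        ]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric entry ({exc})") from None
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged rows, lengths {sorted(lengths)}")
    a = np.array(rows)
    try:
        return as_interaction_matrix(a)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_vector(path) -> np.ndarray:
    """Read a growth-rate vector from CSV/TSV (one line or one per line)."""
    text = Path(path).read_text()
    delim = _sniff_delimiter(text)
    vals = [
        float(x)
        for ln in text.splitlines()
        if ln.strip()
        for x in ln.split(delim)
        if x.strip()
    ]
    return np.array(vals)


def read_system(path, b_path=None) -> tuple[np.ndarray, np.ndarray, list]:
    """Load a system ``(A, b, labels)`` from JSON or delimited text.

    A ``.json`` path is parsed as the single-document form; anything else
    is a headerless matrix file with an optional companion vector file.
    Missing ``b`` defaults to all ones, missing labels to ``"1".."N"``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        if "A" not in doc:
            raise ValueError(f"{path}: JSON system document must contain key 'A'")
        a = as_interaction_matrix(doc["A"])
        b = as_growth_rates(doc.get("b"), a.shape[0])
        labels = doc.get("labels") or [str(i) for i in range(1, a.shape[0] + 1)]
    else:
        a = read_matrix(path)
        b = read_vector(b_path) if b_path is not None else None
        b = as_growth_rates(b, a.shape[0])
        labels = [str(i) for i in range(1, a.shape[0] + 1)]
    if len(labels) != a.shape[0]:
        raise ValueError(f"{path}: {len(labels)} labels for {a.shape[0]} species")
    return a, b, labels


def write_matrix(path, a, delimiter: Optional[str] = None) -> None:
    """Write a matrix as headerless delimited text at full precision."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    a = np.atleast_2d(np.asarray(a, dtype=float))
    lines = [delimiter.join(repr(float(x)) for x in row) for row in a]
    path.write_text("\n".join(lines) + "\n")


def write_system_json(path, a, b=None, labels=None) -> None:
    """Write the JSON system document (full double precision via repr)."""
    a = as_interaction_matrix(a)
    b = as_growth_rates(b, a.shape[0])
    doc = {
        "A": [[float(x) for x in row] for row in a],
        "b": [float(x) for x in b],
        "labels": list(labels) if labels else [str(i) for i in range(1, a.shape[0] + 1)],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def catalog_to_json(catalog) -> str:
    """Serialize a community catalog (admissible + rejected) as JSON."""
    return json.dumps({"n": catalog.n, "communities": catalog.to_records()}, indent=1)
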