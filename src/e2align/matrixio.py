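"""Readers and writers for matrix, parameter, and alignment text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_ncbi_matrix(path) -> tuple[np.ndarray, str]:
    """Read an NCBI-format score matrix (e.g. a BLOSUM62 file).

    Lines starting with ``#`` are comments; the first data line is the
    column alphabet; each subsequent line is a row label followed by
    scores.  Returns (matrix, alphabet) restricted to the row labels.
    """
    alphabet = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if alphabet is None:
                alphabet = "".join(parts)
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if alphabet is None or not rows:
        raise ValueError(f"no matrix data found in {path}")
    labels = "".join(rows)
    cols = [alphabet.index(a) for a in labels]
    mat = np.array([[rows[a][c] for c in cols] for a in labels])
    return mat, labels


def write_ncbi_matrix(path, matrix: np.ndarray, alphabet: str,
                      comment: str = "", integer: bool = False) -> None:
    """Write a matrix in NCBI text format."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("   " + "  ".join(alphabet) + "\n")
        for a, row in zip(alphabet, matrix):
            if integer:
                vals = " ".join(f"{int(round(v)):3d}" for v in row)
            else:
                vals = " ".join(f"{v:8.4f}" for v in row)
            fh.write(f"{a} {vals}\n")


def read_probability_matrix(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a conditional-probability + frequency file.

    Format: optional ``#`` comments; a line ``freq <f1> ... <fK>``; a column
    alphabet line; then one labeled row per residue with K probabilities.
    Returns (P conditional, f, alphabet).
    """
    freqs = None
    alphabet = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "freq":
                freqs = np.array([float(x) for x in parts[1:]])
                continue
            if alphabet is None:
                alphabet = "".join(parts)
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if alphabet is None or freqs is None or not rows:
        raise ValueError(f"incomplete probability file {path}")
    labels = "".join(rows)
    cols = [alphabet.index(a) for a in labels]
    P = np.array([[rows[a][c] for c in cols] for a in labels])
    f = np.array([freqs[alphabet.index(a)] for a in labels])
    return P, f, labels


def write_probability_matrix(path, P: np.ndarray, f: np.ndarray,
                             alphabet: str, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("freq " + " ".join(f"{x:.8f}" for x in f) + "\n")
        fh.write("   " + "        ".join(alphabet) + "\n")
        for a, row in zip(alphabet, P):
            fh.write(f"{a} " + " ".join(f"{v:.8f}" for v in row) + "\n")


def read_params_file(path) -> dict:
    """Read a plain-text ``key = value`` model parameter file.

    ``model`` is kept as a string; everything else is parsed as float.
    """
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            out[key] = val if key == "model" else float(val)
    return out


def write_params_file(path, model_id: str, params: dict,
                      header_lines: tuple[str, ...] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"model = {model_id}\n")
        for key, val in params.items():
            fh.write(f"{key} = {val!r}\n")


def read_reference_alignments(path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read pairwise reference alignments (Stockholm or aligned FASTA).

    Each alignment block must contain exactly two rows; returns a list of
    (row1, row2) aligned strings.  ``fmt`` defaults to Stockholm for
    ``.sto``/``.stk`` files and aligned FASTA otherwise.
    """
    from Bio import AlignIO

    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk")) \
            else "fasta"
    out = []
    for aln in AlignIO.parse(str(path), fmt):
        if len(aln) != 2:
            raise ValueError(
                f"expected pairwise alignments, got {len(aln)} rows in {path}")
        out.append((str(aln[0].seq), str(aln[1].seq)))
    return out


def write_stockholm_pair(path_or_handle, name1: str, row1: str, name2: str,
                         row2: str, homology: str | None = None,
                         gf_lines: tuple[str, ...] = ()) -> None:
    """Write one pairwise alignment in Stockholm format.

    ``homology`` is an optional per-column annotation string (e.g. ``*`` for
    homologous columns, ``.`` for flanks) emitted as a ``#=GC HOM`` line.
    """
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("# STOCKHOLM 1.0\n")
        for line in gf_lines:
            fh.write(f"#=GF {line}\n")
        width = max(len(name1), len(name2), len("#=GC HOM"))
        fh.write(f"{name1:<{width}} {row1}\n")
        fh.write(f"{name2:<{width}} {row2}\n")
        if homology is not None:
            fh.write(f"{'#=GC HOM':<{width}} {homology}\n")
        fh.write("//\n")
    finally:
        if own:
            fh.close()
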