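"""Karyotype representation, distances and neighborhood enumeration.

A karyotype is an ordered vector of integer copy numbers over the 22 human
autosomes (chr1..chr22, no sex chromosomes). It is represented throughout the
package as a plain tuple of 22 non-negative ints, which is hashable and can
therefore key count maps directly. The canonical string form is dot-separated,
e.g. ``"2.2.2....2"`` for the diploid state.

A single chromosome missegregation changes one entry by +/-1, so missegregation
distance between karyotypes equals Manhattan (L1) distance. States containing a
zero copy number are nonviable by default: a cell that has lost every copy of
an autosome cannot survive.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence

import numpy as np

#: number of autosomes tracked per karyotype
N_AUTOSOMES = 22

#: the euploid reference state
DIPLOID = (2,) * N_AUTOSOMES

Karyotype = tuple  # tuple[int, ...] of length N_AUTOSOMES


def parse_karyotype(text: str) -> Karyotype:
    """Parse a dot-separated copy-number string into a karyotype tuple.

    Parameters
    ----------
    text
        Dot-separated integers, e.g. ``"2.2.2. ... .2"`` with exactly 22
        tokens, each a non-negative integer.

    Raises
    ------
    ValueError
        If the token count differs from 22 or any token is not a
        non-negative integer (the offending token is named).
    """
    tokens = text.strip().split(".")
    if len(tokens) != N_AUTOSOMES:
        raise ValueError(
            f"karyotype string must have {N_AUTOSOMES} dot-separated tokens, "
            f"got {len(tokens)}: {text!r}"
        )
    copies = []
    for i, tok in enumerate(tokens):
        try:
            value = int(tok)
        except ValueError:
            raise ValueError(
                f"karyotype token {i + 1} is not an integer: {tok!r}"
            ) from None
        if value < 0:
            raise ValueError(f"karyotype token {i + 1} is negative: {tok!r}")
        copies.append(value)
    return tuple(copies)


def format_karyotype(k: Sequence[int]) -> str:
    """Format a karyotype as the canonical dot-separated string."""
    _check(k)
    return ".".join(str(int(c)) for c in k)


def _check(k: Sequence[int]) -> None:
    if len(k) != N_AUTOSOMES:
        raise ValueError(
            f"karyotype must have length {N_AUTOSOMES}, got {len(k)}"
        )


def is_viable(k: Sequence[int]) -> bool:
    """A karyotype is viable iff every autosome retains at least one copy."""
    return all(c > 0 for c in k)


def manhattan_distance(k1: Sequence[int], k2: Sequence[int]) -> int:
    """Missegregation (Manhattan) distance between two karyotypes."""
    _check(k1)
    _check(k2)
    return int(sum(abs(int(a) - int(b)) for a, b in zip(k1, k2)))


def one_step_neighbors(k: Sequence[int], allow_zero: bool = True) -> set:
    """All karyotypes one missegregation away (+/-1 on one chromosome).

    The diploid state has 44 such neighbors (one gain and one loss per
    autosome). Losses that would drive a copy number negative are never
    generated; with ``allow_zero=False`` losses into zero-copy (nonviable)
    states are excluded as well.
    """
    _check(k)
    k = tuple(int(c) for c in k)
    out = set()
    for i, c in enumerate(k):
        if c >= 1 and (allow_zero or c > 1):
            out.add(k[:i] + (c - 1,) + k[i + 1 :])
        out.add(k[:i] + (c + 1,) + k[i + 1 :])
    return out


def charted_region(
    frequent: Iterable[Karyotype], radius: int = 2, allow_zero: bool = False
) -> set:
    """All viable karyotypes within ``radius`` missegregations of a set.

    This is the union of Manhattan balls around the frequently observed
    clones — the region over which fitness interpolation is attempted
    (default radius 2, i.e. within two missegregations).
    """
    frequent = [tuple(int(c) for c in k) for k in frequent]
    if not frequent:
        raise ValueError("frequent set must be non-empty")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    for k in frequent:
        _check(k)
    seen = set(frequent)
    frontier = deque(frequent)
    for _ in range(radius):
        nxt = deque()
        while frontier:
            k = frontier.popleft()
            for nb in one_step_neighbors(k, allow_zero=True):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    if not allow_zero:
        seen = {k for k in seen if is_viable(k)}
    return seen


def modal_karyotype_from_bins(
    cn_matrix: np.ndarray, bin_chroms: Sequence
) -> list:
    """Collapse per-bin integer copy numbers to per-cell karyotype vectors.

    For every cell and autosome, the karyotype entry is the modal (most
    frequent) integer copy number across that autosome's genomic bins, with
    ties broken toward the smaller value.

    Parameters
    ----------
    cn_matrix
        Integer matrix of shape (cells, bins), non-negative.
    bin_chroms
        Per-bin autosome labels; either integers 1..22 or strings such as
        ``"chr7"`` / ``"7"``. Every autosome must be represented by at least
        one bin.

    Returns
    -------
    list of karyotype tuples, one per cell (row).
    """
    cn = np.asarray(cn_matrix)
    if cn.ndim != 2:
        raise ValueError("cn_matrix must be 2-D (cells x bins)")
    if cn.shape[1] != len(bin_chroms):
        raise ValueError("bin_chroms length must match the number of bins")
    if np.any(cn < 0) or not np.issubdtype(cn.dtype, np.integer):
        cn_int = cn.astype(int)
        if np.any(cn_int != cn) or np.any(cn_int < 0):
            raise ValueError("cn_matrix entries must be non-negative integers")
        cn = cn_int

    labels = []
    for lab in bin_chroms:
        if isinstance(lab, str):
            lab = lab.lower().removeprefix("chr")
        labels.append(int(lab))
    labels = np.asarray(labels)
    present = set(labels.tolist())
    missing = [c for c in range(1, N_AUTOSOMES + 1) if c not in present]
    if missing:
        raise ValueError(f"no bins assigned to autosome(s): {missing}")

    chrom_cols = {c: np.where(labels == c)[0] for c in range(1, N_AUTOSOMES + 1)}
    karyotypes = []
    for row in cn:
        copies = []
        for c in range(1, N_AUTOSOMES + 1):
            vals = row[chrom_cols[c]]
            counts = np.bincount(vals)
            copies.append(int(np.argmax(counts)))  # argmax ties -> smaller
        karyotypes.append(tuple(copies))
    return karyotypes


def state_space_size(n_chrom: int, max_copy: int) -> int:
    """Number of karyotypes with copy numbers 1..max_copy per chromosome.

    Exact integer arithmetic; with 22 chromosomes and up to eight copies each
    this exceeds 10^19 states, which is what makes exhaustive landscape
    mapping infeasible and local inference necessary.
    """
    if n_chrom < 1 or max_copy < 1:
        raise ValueError("n_chrom and max_copy must be >= 1")
    return int(max_copy) ** int(n_chrom)
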