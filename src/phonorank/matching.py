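"""Cross-method phonon mode assignment by eigenvector overlap.

Two lattice-dynamics calculations on the same crystal (e.g. a local-orbital
and a plane-wave method) produce the same physical modes up to reordering,
small frequency shifts and arbitrary eigenvector phases.  Equivalent modes
are identified by the magnitude of the eigenvector dot product: for ideally
equivalent normal modes |e_i . e_j| = 1, for unrelated modes ~ 0.  The
assignment that maximizes the summed overlap over all nontranslational
Gamma modes is a linear sum assignment (Hungarian) problem, solved here
per symmetry block when irreducible-representation labels are present —
modes of different irreps cannot be equivalent, and blocking also shrinks
the problem.

The absolute value of the dot product is used throughout because the
eigenvector sign/phase is arbitrary between codes.  Members of a degenerate
multiplet have basis-dependent individual overlaps; the matcher therefore
also reports a subspace-level overlap per pair (the norm of the overlap row
restricted to the partner modes matched to the multiplet) so degeneracy is
not misread as poor agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .mode_data import ModeSet

__all__ = [
    "Assignment",
    "POOR_OVERLAP_THRESHOLD",
    "overlap_matrix",
    "solve_assignment",
    "match_modesets",
    "overlap_histogram",
    "assignment_matches_truth",
]

logger = logging.getLogger(__name__)

#: Matched overlaps below this value count as "poor".
POOR_OVERLAP_THRESHOLD = 0.4

#: Default frequency window (cm^-1) for the matched-frequency RMSD: the
#: intermolecular (lattice-mode) region.
DEFAULT_RMSD_WINDOW = (0.0, 250.0)

# Lexicographic tie-breaking: the overlap objective dominates; among
# near-equal assignments the solver prefers frequency-proximal pairs, then
# low indices.  Epsilons are small enough not to disturb the primary
# objective for any block solved here.
_TIE_EPS_FREQ = 1e-9
_TIE_EPS_INDEX = 1e-12


@dataclass
class Assignment:
    """A matched permutation between two mode sets.

    ``pairs`` is a list of ``(index_a, index_b, overlap, freq_a, freq_b)``
    with indices into the compared (nontranslational Gamma) mode lists;
    together they form a bijection.  ``rmsd`` is the root-mean-square
    frequency deviation over matched pairs whose reference (set a)
    frequency lies inside ``window``.
    """

    pairs: List[Tuple[int, int, float, float, float]]
    block_labels: List[Optional[str]]
    rmsd: float
    window: Tuple[float, float]
    subspace_overlaps: List[float] = field(default_factory=list)

    @property
    def permutation(self) -> np.ndarray:
        """Array p with p[index_a] = index_b."""
        p = np.full(len(self.pairs), -1, dtype=int)
        for ia, ib, *_ in self.pairs:
            p[ia] = ib
        return p

    @property
    def overlaps(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])


def overlap_matrix(a: ModeSet, b: ModeSet, block: Optional[str] = None) -> np.ndarray:
    """|e_i^a . e_j^b| over the nontranslational Gamma modes.

    When ``block`` is given, rows/columns are restricted to modes carrying
    that irrep label.  The sets must share atom count and checksum (atom
    ordering is part of the comparability contract).
    """
    a.require_comparable(b)
    modes_a = _compared_modes(a, block)
    modes_b = _compared_modes(b, block)
    if not modes_a or not modes_b:
        return np.zeros((len(modes_a), len(modes_b)))
    ea = np.stack([m.eigenvector for m in modes_a])
    eb = np.stack([m.eigenvector for m in modes_b])
    # unit vectors can overshoot 1 by rounding; the overlap is defined in [0, 1]
    return np.clip(np.abs(ea @ eb.T), 0.0, 1.0)


def _compared_modes(ms: ModeSet, block: Optional[str] = None):
    modes = ms.gamma_modes(include_translations=False)
    if block is not None:
        modes = [m for m in modes if m.irrep == block]
    return modes


def solve_assignment(
    overlaps: np.ndarray,
    freqs_a: Optional[Sequence[float]] = None,
    freqs_b: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Permutation maximizing the summed overlap.

    Rectangular inputs are padded with zero-overlap dummy entries; dummy
    pairings are dropped from the returned permutation, which maps row
    ``i`` to column ``perm[i]`` (or -1 for unmatched rows).  Ties in the
    overlap objective are broken toward the pairing minimizing
    |freq_a - freq_b| (when frequencies are supplied), then toward the
    lowest column index.
    """
    overlaps = np.asarray(overlaps, dtype=float)
    if overlaps.size == 0:
        return np.full(overlaps.shape[0] if overlaps.ndim else 0, -1, dtype=int)
    n_r, n_c = overlaps.shape
    n = max(n_r, n_c)
    padded = np.zeros((n, n))
    padded[:n_r, :n_c] = overlaps

    cost = -padded.copy()
    if freqs_a is not None and freqs_b is not None:
        fa = np.asarray(freqs_a, dtype=float)
        fb = np.asarray(freqs_b, dtype=float)
        gap = np.abs(fa[:, None] - fb[None, :])
        span = gap.max()
        if span > 0:
            cost[:n_r, :n_c] += _TIE_EPS_FREQ * gap / span
    # lexicographic index preference: earlier rows grab lower column indices
    # among otherwise-equal optima (a separable i+j penalty would be
    # permutation-invariant, so the weights must couple row and column)
    cost += _TIE_EPS_INDEX * np.outer(np.arange(n, 0, -1), np.arange(n)) / (n * n)

    rows, cols = linear_sum_assignment(cost)
    perm = np.full(n_r, -1, dtype=int)
    for r, c in zip(rows, cols):
        if r < n_r and c < n_c:
            perm[r] = c
    return perm


def match_modesets(
    a: ModeSet,
    b: ModeSet,
    window: Tuple[float, float] = DEFAULT_RMSD_WINDOW,
    degeneracy_tol: float = 1e-6,
) -> Assignment:
    """Assign the nontranslational Gamma modes of ``b`` to those of ``a``.

    The assignment is solved per irreducible-representation block when both
    sets carry labels; if either set lacks them the solver falls back to a
    single global block with a logged warning (symmetry blocking is both a
    physical constraint and an optimization, never silently required).

    ``rmsd`` is computed over matched pairs whose reference frequency
    (set a) lies in ``window``; with no such pairs it is NaN.
    """
    a.require_comparable(b)
    modes_a = _compared_modes(a)
    modes_b = _compared_modes(b)
    if len(modes_a) != len(modes_b):
        raise ValueError(
            f"cannot match {len(modes_a)} vs {len(modes_b)} nontranslational modes"
        )

    labels_a = {m.irrep for m in modes_a}
    labels_b = {m.irrep for m in modes_b}
    use_blocks = None not in labels_a and None not in labels_b
    if not use_blocks and (None in labels_a) != (None in labels_b):
        logger.warning(
            "only one mode set carries irrep labels; falling back to a single "
            "global assignment block"
        )

    full_overlaps = overlap_matrix(a, b)
    pairs: List[Tuple[int, int, float, float, float]] = []
    block_labels: List[Optional[str]] = []

    if use_blocks:
        if labels_a != labels_b:
            raise ValueError(
                f"irrep label sets differ: {sorted(labels_a)} vs {sorted(labels_b)}"
            )
        blocks = sorted(labels_a)
    else:
        blocks = [None]

    for label in blocks:
        idx_a = [
            i for i, m in enumerate(modes_a) if not use_blocks or m.irrep == label
        ]
        idx_b = [
            j for j, m in enumerate(modes_b) if not use_blocks or m.irrep == label
        ]
        sub = full_overlaps[np.ix_(idx_a, idx_b)]
        fa = [modes_a[i].frequency for i in idx_a]
        fb = [modes_b[j].frequency for j in idx_b]
        perm = solve_assignment(sub, fa, fb)
        for r, c in enumerate(perm):
            if c < 0:
                continue
            ia, ib = idx_a[r], idx_b[c]
            pairs.append(
                (
                    ia,
                    ib,
                    float(full_overlaps[ia, ib]),
                    modes_a[ia].frequency,
                    modes_b[ib].frequency,
                )
            )
            block_labels.append(label)

    pairs_sorted = sorted(zip(pairs, block_labels), key=lambda t: t[0][0])
    pairs = [p for p, _ in pairs_sorted]
    block_labels = [lbl for _, lbl in pairs_sorted]

    # subspace-level overlap: for each pair, the norm of a-mode i's overlap
    # row over the b-modes matched to i's degenerate multiplet in a
    match_of = {ia: ib for ia, ib, *_ in pairs}
    freqs_a_arr = np.array([m.frequency for m in modes_a])
    subspace = []
    for ia, ib, *_ in pairs:
        cluster = np.flatnonzero(
            np.abs(freqs_a_arr - freqs_a_arr[ia]) <= degeneracy_tol
        )
        partner_cols = [match_of[i] for i in cluster if i in match_of]
        row = full_overlaps[ia, partner_cols]
        subspace.append(float(np.sqrt(np.sum(row**2))))

    in_window = [
        (fa - fb) for _, _, _, fa, fb in pairs if window[0] <= fa <= window[1]
    ]
    rmsd = float(np.sqrt(np.mean(np.square(in_window)))) if in_window else float("nan")

    return Assignment(
        pairs=pairs,
        block_labels=block_labels,
        rmsd=rmsd,
        window=tuple(window),
        subspace_overlaps=subspace,
    )


def assignment_matches_truth(
    a: ModeSet, b: ModeSet, asg: Assignment, truth: np.ndarray
) -> bool:
    """Check an assignment against a generator ground-truth permutation.

    ``truth`` maps global mode indices of ``b`` to their origin in ``a``
    (as returned by the synthetic method-change perturbation).  Assignment
    pair indices refer to the compared nontranslational Gamma mode lists,
    so they are lifted to global indices first.
    """
    glob_a = [
        i
        for i, m in enumerate(a.modes)
        if m.qpoint_index == a.gamma_index and not m.is_translation
    ]
    glob_b = [
        j
        for j, m in enumerate(b.modes)
        if m.qpoint_index == b.gamma_index and not m.is_translation
    ]
    return all(truth[glob_b[ib]] == glob_a[ia] for ia, ib, *_ in asg.pairs)


@dataclass
class OverlapHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray
    n_poor: int                 # matched overlaps below the poor threshold
    poor_threshold: float


def overlap_histogram(
    asg: Assignment,
    bin_edges: Sequence[float] = tuple(np.linspace(0.0, 1.0, 11)),
    poor_threshold: float = POOR_OVERLAP_THRESHOLD,
) -> OverlapHistogram:
    """Histogram of matched overlaps plus the count of poor (< 0.4) pairs."""
    ov = asg.overlaps
    counts, edges = np.histogram(ov, bins=np.asarray(bin_edges, dtype=float))
    return OverlapHistogram(
        counts=counts,
        bin_edges=edges,
        n_poor=int(np.sum(ov < poor_threshold)),
        poor_threshold=poor_threshold,
    )
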