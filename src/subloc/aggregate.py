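"""Protein-level localization calls from per-cell class probabilities.

Each cell's localization is modeled as a draw from a multinomial over the K
compartments; with a symmetric (uninformative) Dirichlet prior on the
protein's compartment frequencies, the posterior concentration is the prior
plus the soft count of cells per compartment — the sum of the per-cell
probability vectors. The protein's compartment call is the maximum a
posteriori compartment, i.e. the one with the largest soft count; the
posterior mass fractions are interpretable as the frequency of cells in
which the protein resides in each compartment, so dual-localized proteins
surface naturally in the top-k report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("subloc")


@dataclass
class ClassProbabilities:
    """One cell's probability simplex over the K compartments."""

    probs: np.ndarray
    cell_id: str = ""
    protein_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {self.probs.sum()!r}")


@dataclass
class DirichletPosterior:
    """Posterior concentration over compartments for one protein."""

    alpha: np.ndarray
    n_cells: int
    prior_alpha: float
    protein_id: str = ""

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if np.any(self.alpha < self.prior_alpha - 1e-9):
            raise ValueError("posterior concentrations cannot fall below the prior")


def dirichlet_posterior(
    cells: Sequence[ClassProbabilities],
    prior_alpha: float = 1.0,
    n_classes: int | None = None,
    hard: bool = False,
) -> DirichletPosterior:
    """Posterior concentration: prior plus soft counts.

    ``alpha_k = prior_alpha + sum_cells probs_k``. With ``hard=True`` each
    cell contributes a one-hot vector at its argmax instead of its full
    probability vector (hard counting, for comparison). An empty cell list
    returns the prior with a logged warning.
    """
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    if not cells:
        if n_classes is None:
            raise ValueError("empty cell list needs an explicit n_classes")
        logger.warning("empty cell list: posterior equals the prior")
        return DirichletPosterior(
            alpha=np.full(n_classes, prior_alpha), n_cells=0, prior_alpha=prior_alpha
        )
    proteins = {c.protein_id for c in cells}
    if len(proteins) > 1:
        raise ValueError(f"cells mix protein_ids {sorted(proteins)}")
    K = len(cells[0].probs)
    if n_classes is not None and n_classes != K:
        raise ValueError(f"probability vectors have length {K}, expected {n_classes}")
    counts = np.zeros(K)
    for c in cells:
        if len(c.probs) != K:
            raise ValueError("inconsistent probability vector lengths")
        if hard:
            counts[int(np.argmax(c.probs))] += 1.0
        else:
            counts += c.probs
    return DirichletPosterior(
        alpha=prior_alpha + counts,
        n_cells=len(cells),
        prior_alpha=prior_alpha,
        protein_id=cells[0].protein_id,
    )


def map_compartment(
    posterior: DirichletPosterior, class_order: Sequence[str] | None = None
) -> tuple[str | int, bool]:
    """Maximum a posteriori compartment: argmax of the concentration.

    Returns ``(label_or_index, tie_flag)``; exact ties resolve to the
    lowest class index and are flagged. Refuses to call a protein with no
    observed cells.
    """
    if posterior.n_cells < 1:
        raise ValueError("cannot call a protein with zero observed cells")
    idx = int(np.argmax(posterior.alpha))
    tie = bool(np.sum(posterior.alpha == posterior.alpha[idx]) > 1)
    if tie:
        logger.warning("tied MAP compartments for %s", posterior.protein_id or "<protein>")
    label = class_order[idx] if class_order is not None else idx
    return label, tie


def top_k_classes(
    posterior: DirichletPosterior, k: int, class_order: Sequence[str] | None = None
) -> list[tuple[str | int, float]]:
    """Top-k compartments by posterior concentration with mass fractions.

    The mass fraction ``(alpha_k - prior) / sum(alpha - prior)`` estimates
    the frequency of cells in which the protein resides in compartment k.
    With ``k = K`` the fractions sum to 1.
    """
    K = len(posterior.alpha)
    if not (1 <= k <= K):
        raise ValueError(f"k must be in [1, {K}], got {k}")
    excess = posterior.alpha - posterior.prior_alpha
    total = excess.sum()
    fractions = excess / total if total > 0 else np.full(K, np.nan)
    order = np.argsort(-posterior.alpha, kind="stable")[:k]
    return [
        (class_order[i] if class_order is not None else int(i), float(fractions[i]))
        for i in order
    ]


def filter_min_cells(
    posteriors: Sequence[DirichletPosterior], min_cells: int
) -> list[DirichletPosterior]:
    """Drop proteins observed in fewer than ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    kept = [p for p in posteriors if p.n_cells >= min_cells]
    removed = len(posteriors) - len(kept)
    if removed:
        logger.info("min-cell filter removed %d of %d proteins", removed, len(posteriors))
    if not kept:
        logger.warning("min-cell filter removed every protein")
    return kept


def aggregate_proteins(
    probs: np.ndarray,
    protein_ids: Sequence[str],
    class_order: Sequence[str],
    prior_alpha: float = 1.0,
    hard: bool = False,
) -> dict[str, DirichletPosterior]:
    """Group per-cell probability rows by protein and form posteriors."""
    probs = np.asarray(probs)
    out: dict[str, DirichletPosterior] = {}
    protein_ids = np.asarray(protein_ids)
    for pid in dict.fromkeys(protein_ids):  # stable order
        rows = probs[protein_ids == pid]
        cells = [ClassProbabilities(r, protein_id=pid) for r in rows]
        out[pid] = dirichlet_posterior(cells, prior_alpha, n_classes=len(class_order), hard=hard)
    return out
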