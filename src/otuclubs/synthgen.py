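"""Synthetic abundance matrices with planted clubs, rivals, and leaders.

A latent-factor construction on the log-abundance scale: each club has one
shared standard-normal factor per sample, and a member's latent value is
``loading * factor + sqrt(1 - loading^2) * noise`` with
``loading = sqrt(target_intra_r)``, so the expected pairwise correlation
between members equals the target.  A rival club pair (a, b) gives b's
members an extra negative loading on a's factor chosen so the expected
cross correlation equals the (negative) inter target.  One designated
leader per club gets a boosted own-factor loading, making its correlations
dominate.  Latent values are shifted by per-OTU baselines spanning several
orders of magnitude, exponentiated to expected proportions, and counts are
drawn per sample as a multinomial at the requested depth; structural zeros
are injected at the proportion level so sample totals stay at depth.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_abundance import AbundanceMatrix

__all__ = ["CommunitySpec", "PlantedTruth", "generate_community", "write_truth_tsv"]


class InfeasibleSpecError(ValueError):
    """Correlation targets that no loading vector can realize."""


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic study group.

    clubs: one (size, target intra correlation) per planted club, size >= 3,
    target in (0, 1).  rival_pairs: ((club_i, club_j), target inter
    correlation in (-1, 0)).  leader_boost adds own-factor loading to one
    designated member per club.  sparsity is the fraction of structural
    zeros injected into the proportion matrix.
    """

    n_samples: int = 100
    clubs: tuple[tuple[int, float], ...] = ((8, 0.6),)
    rival_pairs: tuple[tuple[tuple[int, int], float], ...] = ()
    leader_boost: float = 0.0
    n_background: int = 20
    depth: int = 50_000
    sparsity: float = 0.0
    seed: int = 0
    group: str = "group1"
    baseline_sd: float = 1.0
    filler_share: float = 0.7

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        for size, rho in self.clubs:
            if size < 3:
                raise ValueError(f"club size {size} < 3")
            if not 0 < rho < 1:
                raise ValueError(f"intra target {rho} outside (0, 1)")
        for (a, b), t in self.rival_pairs:
            if not 0 <= a < len(self.clubs) or not 0 <= b < len(self.clubs) or a == b:
                raise ValueError(f"bad rival club indices ({a}, {b})")
            if not -1 < t < 0:
                raise ValueError(f"inter target {t} outside (-1, 0)")
        if self.leader_boost < 0:
            raise ValueError("leader_boost must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if not 0 <= self.filler_share < 1:
            raise ValueError("filler_share must be in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground-truth labels for generator output."""

    club_of: dict[str, int]  # OTU -> club index; -1 for background
    leaders: dict[int, str]  # club index -> leader OTU
    rival_pairs: list[tuple[int, int]] = field(default_factory=list)

    def labels(self, otu_ids: list[str]) -> np.ndarray:
        return np.array([self.club_of.get(o, -1) for o in otu_ids])


def _loadings(spec: CommunitySpec) -> tuple[np.ndarray, list[str], PlantedTruth]:
    """Build the (n_otus x n_factors) loading matrix, OTU names, and truth."""
    n_clubs = len(spec.clubs)
    sizes = [s for s, _ in spec.clubs]
    n_otus = sum(sizes) + spec.n_background
    lam = np.zeros((n_otus, n_clubs))
    otu_ids: list[str] = []
    club_of: dict[str, int] = {}
    leaders: dict[int, str] = {}

    row = 0
    for ci, (size, rho) in enumerate(spec.clubs):
        base = np.sqrt(rho)
        for j in range(size):
            name = f"Club{ci}_OTU{j + 1}"
            otu_ids.append(name)
            club_of[name] = ci
            loading = base
            if j == 0:  # first member is the designated leader
                loading = min(base + spec.leader_boost, 0.995)
                leaders[ci] = name
            lam[row, ci] = loading
            row += 1
    for j in range(spec.n_background):
        name = f"Bg_OTU{j + 1}"
        otu_ids.append(name)
        club_of[name] = -1
        row += 1

    # rival pairs: club b loads negatively on club a's factor so that the
    # expected cross correlation base_a * load_ba equals the target
    offsets = np.cumsum([0] + sizes)
    for (a, b), target in spec.rival_pairs:
        rho_a, rho_b = spec.clubs[a][1], spec.clubs[b][1]
        load_ba = target / np.sqrt(rho_a)
        if load_ba**2 >= rho_b:
            raise InfeasibleSpecError(
                f"inter target {target} needs cross-loading^2 = {load_ba**2:.3f}"
                f" >= intra target {rho_b} of club {b}"
            )
        for r in range(offsets[b], offsets[b] + sizes[b]):
            lam[r, a] = load_ba
            # shrink own-factor loading so total intra-b correlation stays rho_b
            own = rho_b - load_ba**2
            base = lam[r, b]
            boosted = base > np.sqrt(rho_b) + 1e-12  # leader keeps its boost
            lam[r, b] = min(base, np.sqrt(own)) if not boosted else base

    if np.any((lam**2).sum(axis=1) >= 1.0):
        bad = int(np.argmax((lam**2).sum(axis=1)))
        raise InfeasibleSpecError(
            f"OTU {otu_ids[bad]} needs loading^2 sum "
            f"{(lam[bad] ** 2).sum():.3f} >= 1; relax the targets"
        )
    truth = PlantedTruth(club_of, leaders, [pair for pair, _ in spec.rival_pairs])
    return lam, otu_ids, truth


def generate_community(spec: CommunitySpec) -> tuple[AbundanceMatrix, PlantedTruth]:
    """Draw one abundance matrix plus its ground truth from the spec."""
    rng = np.random.default_rng(spec.seed)
    lam, otu_ids, truth = _loadings(spec)
    n_otus, n_factors = lam.shape
    n = spec.n_samples

    factors = rng.standard_normal((n, n_factors))
    noise_sd = np.sqrt(1.0 - (lam**2).sum(axis=1))
    z = factors @ lam.T + rng.standard_normal((n, n_otus)) * noise_sd

    # per-OTU baselines spread abundances over several orders of magnitude
    # (kept narrow enough that rare OTUs retain the read counts needed to
    # carry their planted correlations through multinomial sampling)
    mu = rng.normal(0.0, spec.baseline_sd * 1.2, size=n_otus)
    log_abund = mu + spec.baseline_sd * z
    expected = np.exp(log_abund)
    if spec.sparsity > 0:
        zero_mask = rng.random((n, n_otus)) < spec.sparsity
        expected = np.where(zero_mask, 0.0, expected)
        # guard: a fully zeroed sample is resampled as all-present
        dead = expected.sum(axis=1) == 0
        expected[dead] = np.exp(log_abund[dead])
    if spec.filler_share > 0:
        # a constant dominant taxon stabilizes the per-sample total so that
        # compositional closure does not induce spurious inter-club
        # correlations among the planted OTUs
        filler = (
            spec.filler_share
            / (1.0 - spec.filler_share)
            * float(expected.sum(axis=1).mean())
        )
        expected = np.hstack([expected, np.full((n, 1), filler)])
        otu_ids = otu_ids + ["Other"]
        truth.club_of["Other"] = -1
        n_otus += 1
    proportions = expected / expected.sum(axis=1, keepdims=True)

    counts = np.empty((n, n_otus), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(spec.depth, proportions[i])

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    m = AbundanceMatrix(
        sample_ids, otu_ids, counts, {s: spec.group for s in sample_ids}
    )
    return m, truth


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    rows = [
        {
            "otu_id": otu,
            "club_id": club,
            "is_leader": int(truth.leaders.get(club) == otu),
        }
        for otu, club in truth.club_of.items()
    ]
    df = pd.DataFrame(rows, columns=["otu_id", "club_id", "is_leader"])
    df.to_csv(path, sep="\t", index=False)
    rivals = pd.DataFrame(
        [{"club_a": a, "club_b": b} for a, b in truth.rival_pairs],
        columns=["club_a", "club_b"],
    )
    rivals_path = Path(path).with_suffix(".rivals.tsv")
    rivals.to_csv(rivals_path, sep="\t", index=False)
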