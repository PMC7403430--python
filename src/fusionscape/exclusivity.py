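"""Bootstrap test of mutual exclusivity among resistance alterations.

Three TMZ-resistance mechanisms — MGMT promoter hypomethylation, DNA
hypermutation, and MGMT fusion — are tested for mutual exclusivity with a
coverage statistic: the number of patients carrying at least one of the
alterations. If the alterations avoid each other, their union covers more
patients than random placement of the same marginal counts would.

The null keeps each alteration's positive count fixed and reassigns its
positive patients uniformly at random (without replacement) within that
alteration's assayed set, independently across alterations. The empirical
P-value is the fraction of randomisations whose coverage strictly exceeds
the observed coverage, over 10,000 replicates by default — so a maximally
exclusive configuration yields P = 0, reported as P < 1/n_reps.

:func:`enumerate_exclusivity_exact` computes the same tail probability by
exhaustive enumeration on small instances and serves as the independent
oracle for the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "ExclusivityInput",
    "ExclusivityTest",
    "coverage",
    "bootstrap_exclusivity",
    "enumerate_exclusivity_exact",
    "exclusivity_from_landscape",
]


@dataclass
class ExclusivityInput:
    """Positive and assayed patient sets per alteration.

    Patients are arbitrary hashables; for each alteration,
    positives ⊆ assayed ⊆ the full patient universe of size ``n_patients``.
    """

    n_patients: int
    alterations: dict[str, tuple[frozenset, frozenset]]  # name -> (positives, assayed)
    patients: tuple = ()

    def __post_init__(self):
        if not self.patients:
            self.patients = tuple(range(self.n_patients))
        if len(self.patients) != self.n_patients:
            raise ValueError("patients tuple must have length n_patients")
        universe = set(self.patients)
        for name, (pos, assayed) in self.alterations.items():
            pos, assayed = frozenset(pos), frozenset(assayed)
            if not pos <= assayed:
                raise ValueError(f"{name}: positives not a subset of assayed")
            if not assayed <= universe:
                raise ValueError(f"{name}: assayed patients outside the cohort")
            self.alterations[name] = (pos, assayed)

    def _indexed(self) -> list[tuple[np.ndarray, int]]:
        """(assayed index array, positive count) per alteration, all scopes applied."""
        index = {p: i for i, p in enumerate(self.patients)}
        out = []
        for pos, assayed in self.alterations.values():
            out.append(
                (np.fromiter(sorted(index[p] for p in assayed), dtype=np.intp), len(pos))
            )
        return out


@dataclass
class ExclusivityTest:
    """Result of the randomisation test.

    ``p_value`` counts replicates whose coverage *strictly* exceeds the
    observed coverage, the published convention; because coverage is a
    discrete statistic with sizeable atoms, this p is anticonservative near
    those atoms (in the degenerate single-alteration case it is identically
    0). ``p_tie_inclusive`` counts ties as well (coverage >= observed) and
    is superuniform under the null; it is the variant to use when calibrated
    type-I control matters. ``p_smoothed`` is the add-one version of the
    strict p, never exactly zero.
    """

    observed_coverage: int
    n_reps: int
    n_greater: int
    p_value: float
    p_smoothed: float  # (n_greater + 1) / (n_reps + 1), never exactly zero
    n_greater_equal: int = 0
    p_tie_inclusive: float = 1.0
    seed: int | None = None
    null_coverage_summary: dict = field(default_factory=dict)
    scope: str = "assayed"


def coverage(inp: ExclusivityInput) -> int:
    """Number of patients carrying at least one alteration (union size)."""
    union: set = set()
    for pos, _ in inp.alterations.values():
        union |= pos
    return len(union)


def _null_coverages(
    inp: ExclusivityInput, n_reps: int, rng: np.random.Generator, scope: str
) -> np.ndarray:
    """Coverage of each randomised replicate, vectorised over replicates."""
    covered = np.zeros((n_reps, inp.n_patients), dtype=bool)
    everyone = np.arange(inp.n_patients, dtype=np.intp)
    for assayed_idx, k in inp._indexed():
        pool = everyone if scope == "all" else assayed_idx
        if k == 0:
            continue
        if k >= pool.size:
            covered[:, pool] = True
            continue
        # random k-subset per replicate: k smallest of i.i.d. uniforms
        u = rng.random((n_reps, pool.size))
        chosen = pool[np.argpartition(u, k - 1, axis=1)[:, :k]]
        covered[np.repeat(np.arange(n_reps), k), chosen.ravel()] = True
    return covered.sum(axis=1)


def bootstrap_exclusivity(
    inp: ExclusivityInput,
    n_reps: int = 10_000,
    seed: int | None = None,
    scope: str = "assayed",
) -> ExclusivityTest:
    """Randomisation test of mutual exclusivity.

    Each replicate reassigns every alteration's positive count uniformly at
    random without replacement within its assayed set (``scope="assayed"``,
    the default) or across all patients (``scope="all"``); coverage is
    counted over all patients. P = #{replicates with coverage > observed} /
    n_reps — strictly greater, so P can be exactly 0; ``p_smoothed`` is the
    add-one alternative for downstream use.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if scope not in {"assayed", "all"}:
        raise ValueError("scope must be 'assayed' or 'all'")
    observed = coverage(inp)
    rng = np.random.default_rng(seed)
    cov = _null_coverages(inp, n_reps, rng, scope)
    n_greater = int((cov > observed).sum())
    n_greater_equal = int((cov >= observed).sum())
    return ExclusivityTest(
        observed_coverage=observed,
        n_reps=n_reps,
        n_greater=n_greater,
        p_value=n_greater / n_reps,
        p_smoothed=(n_greater + 1) / (n_reps + 1),
        n_greater_equal=n_greater_equal,
        p_tie_inclusive=n_greater_equal / n_reps,
        seed=seed,
        null_coverage_summary={
            "mean": float(cov.mean()),
            "sd": float(cov.std(ddof=1)) if n_reps > 1 else 0.0,
            "max": int(cov.max()),
        },
        scope=scope,
    )


def enumerate_exclusivity_exact(
    inp: ExclusivityInput, scope: str = "assayed", max_states: int = 1_000_000
) -> float:
    """Exact P(coverage > observed) by exhausting every joint reassignment.

    All placements of each alteration's positives within its assayed set are
    equiprobable and independent across alterations. Refuses instances whose
    joint state count exceeds ``max_states``.
    """
    observed = coverage(inp)
    index = {p: i for i, p in enumerate(inp.patients)}
    pools = []
    total_states = 1
    for pos, assayed in inp.alterations.values():
        pool = (
            list(range(inp.n_patients))
            if scope == "all"
            else sorted(index[p] for p in assayed)
        )
        k = len(pos)
        total_states *= comb(len(pool), k)
        pools.append((pool, k))
    if total_states > max_states:
        raise ValueError(
            f"enumeration size {total_states} exceeds limit {max_states}"
        )

    # per-alteration list of candidate positive-sets as bitmasks
    mask_lists = []
    for pool, k in pools:
        masks = []
        for combo in combinations(pool, k):
            m = 0
            for i in combo:
                m |= 1 << i
            masks.append(m)
        mask_lists.append(masks)

    def count_exceeding(prefix_mask: int, depth: int) -> int:
        if depth == len(mask_lists):
            return 1 if bin(prefix_mask).count("1") > observed else 0
        return sum(
            count_exceeding(prefix_mask | m, depth + 1) for m in mask_lists[depth]
        )

    return count_exceeding(0, 0) / total_states


def exclusivity_from_landscape(
    landscape: pd.DataFrame, alterations: list[str]
) -> ExclusivityInput:
    """Build the test input from a landscape frame ({yes,no,NA} columns).

    The randomised unit is the patient: a patient is positive for "fusion"
    whether they carry one fusion or two. NA marks a patient as not assayed
    for that alteration.
    """
    patients = tuple(landscape["patient_id"].astype(str))
    alt = {}
    for name in alterations:
        values = landscape[name].astype(str)
        positives = frozenset(landscape.loc[values == "yes", "patient_id"].astype(str))
        assayed = frozenset(landscape.loc[values != "NA", "patient_id"].astype(str))
        alt[name] = (positives, assayed)
    return ExclusivityInput(n_patients=len(patients), alterations=alt, patients=patients)
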