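"""End-to-end evaluation: scores, random nulls, aggregation, curves.

The central question is how well a reconstructed binary tree matches a
partially resolved expert classification. :func:`score_inference` computes
the generalized scores (and optionally the standard ones);
:func:`random_null` calibrates them against completely random binary trees
on the same leaves, because agreeing with a coarse classification is much
easier than agreeing with a fine one; :func:`normalized_accuracy` folds the
two into a single accuracy in [0, 1]; :func:`aggregate_scores` produces the
per-group mean/variance summaries; and :func:`completeness_curve` re-runs
the whole pipeline on progressively longer ranked word lists to expose the
effect of database completeness and coverage.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateNormalizerError,
    LexitreeError,
    NoOverlapError,
)
from .reconstruct import neighbor_joining
from .scores import gqd_score, grf_score, qd_distance, rf_distance
from .trees import (
    PhyloTree,
    prune_to_common_leaves,
    random_binary_tree,
    resolution_fraction,
)
from .wordlists import (
    LexicalDataset,
    build_distance_matrix,
    coverage,
    effective_size,
    select_top_meanings,
)

__all__ = [
    "ScoreReport",
    "NullSummary",
    "GroupSummary",
    "UNRESOLVED",
    "score_inference",
    "random_null",
    "normalized_accuracy",
    "aggregate_scores",
    "completeness_curve",
]


class _Unresolved:
    """Sentinel: the reference is a star, so no accuracy can be defined."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNRESOLVED"


UNRESOLVED = _Unresolved()


@dataclass(frozen=True)
class ScoreReport:
    """Scores of one (reference, inferred) pair after pruning to common leaves."""

    grf: float
    gqd: float
    n_leaves: int
    reference_resolution: float
    rf: float | None = None
    qd: float | None = None


@dataclass(frozen=True)
class NullSummary:
    """Random-tree null: moments of GRF/GQD over R random binary trees."""

    mean_grf_random: float
    var_grf_random: float
    mean_gqd_random: float
    var_gqd_random: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class GroupSummary:
    """Mean and variance of each score across the families of one group."""

    group: str
    n_families: int
    means: Mapping[str, float]
    variances: Mapping[str, float]
    families: tuple[str, ...]


def score_inference(
    reference: PhyloTree,
    inferred: PhyloTree,
    include_standard: bool = False,
    prune: bool = True,
) -> ScoreReport:
    """GRF and GQD of an inferred tree against a reference classification.

    Leaf sets are pruned to their intersection by default (with a warning
    listing dropped languages); ``include_standard`` adds the symmetric RF
    and QD for comparison.
    """
    if prune and reference.leaves != inferred.leaves:
        dropped = sorted(reference.leaves ^ inferred.leaves)
        warnings.warn(
            f"pruning to common leaves; dropped: {dropped}", stacklevel=2
        )
        reference, inferred = prune_to_common_leaves(reference, inferred)
    n = len(reference.leaves)
    if n < 4:
        raise LexitreeError("scoring needs at least 4 shared leaves")
    ref_resolution = resolution_fraction(reference)
    gqd = gqd_score(reference, inferred)
    from .scores import internal_bipartitions  # local to avoid cycle noise

    if internal_bipartitions(reference):
        grf = grf_score(reference, inferred)
    else:
        grf = 0.0  # star reference: every inferred split vacuously compatible
    return ScoreReport(
        grf=grf,
        gqd=gqd,
        n_leaves=n,
        reference_resolution=ref_resolution,
        rf=rf_distance(reference, inferred) if include_standard else None,
        qd=qd_distance(reference, inferred) if include_standard else None,
    )


def _replicate_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def random_null(
    reference: PhyloTree, replicates: int = 10, seed: int = 0
) -> NullSummary:
    """Moments of GRF/GQD for random binary trees on the reference's leaves.

    Replicate seeds are derived deterministically from ``(seed, index)``.
    Against a star reference every random tree scores 0 on both measures,
    so the null mean is exactly 0 (the completely-unresolved case).
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    grfs, gqds = [], []
    for k in range(replicates):
        tree = random_binary_tree(
            reference.leaves, _replicate_seed(seed, k)
        )
        report = score_inference(reference, tree, prune=False)
        grfs.append(report.grf)
        gqds.append(report.gqd)
    return NullSummary(
        mean_grf_random=float(np.mean(grfs)),
        var_grf_random=float(np.var(grfs)),
        mean_gqd_random=float(np.mean(gqds)),
        var_gqd_random=float(np.var(gqds)),
        replicates=replicates,
        seed=seed,
    )


def normalized_accuracy(report: ScoreReport, null: NullSummary):
    """Accuracy relative to the random null: ``clip(1 - 2 GQD / <GQD_rand>)``.

    The factor 2 stretches the scale so that 0 already marks a
    reconstruction no better than half the random-tree distance; values are
    clipped to [0, 1]. When the null mean is 0 (star classification) the
    accuracy is undefined and the :data:`UNRESOLVED` sentinel is returned.
    """
    if null.mean_gqd_random == 0:
        return UNRESOLVED
    return float(
        np.clip(1.0 - 2.0 * report.gqd / null.mean_gqd_random, 0.0, 1.0)
    )


def aggregate_scores(
    reports: Mapping[str, ScoreReport],
    groups: Mapping[str, str],
    ddof: int = 0,
) -> list[GroupSummary]:
    """Per-group mean and variance of each score across member families.

    ``ddof=0`` (population variance) is the default; pass ``ddof=1`` for
    the sample variance. Every family must carry a group label.
    """
    missing = [fam for fam in reports if fam not in groups]
    if missing:
        raise LexitreeError(f"families without a group label: {missing}")
    by_group: dict[str, list[str]] = {}
    for fam in reports:
        by_group.setdefault(groups[fam], []).append(fam)
    out = []
    for group in sorted(by_group):
        fams = sorted(by_group[group])
        members = [reports[f] for f in fams]
        fields = ["grf", "gqd"]
        if all(m.rf is not None for m in members):
            fields += ["rf", "qd"]
        means, variances = {}, {}
        for name in fields:
            vals = np.array([getattr(m, name) for m in members], dtype=float)
            means[name] = float(vals.mean())
            variances[name] = float(vals.var(ddof=ddof)) if len(vals) > ddof else 0.0
        out.append(
            GroupSummary(
                group=group,
                n_families=len(fams),
                means=means,
                variances=variances,
                families=tuple(fams),
            )
        )
    return out


def completeness_curve(
    ds: LexicalDataset,
    reference: PhyloTree,
    ns: Sequence[int],
    method: str = "ldn",
    synonym_rule: str = "first",
    seed: int | None = None,
) -> pd.DataFrame:
    """Accuracy of the full pipeline vs the number of retained meanings.

    For each N in the ascending list *ns*: keep the N most shared meanings,
    build the distance matrix, run NJ and score against the reference;
    report alongside the truncated dataset's effective size N_eff and
    coverage. An N at which some language pair loses all shared meanings
    yields a row with NaN scores rather than aborting the curve. The whole
    procedure is deterministic; *seed* is accepted for interface symmetry
    and unused.
    """
    ns = list(ns)
    if ns != sorted(ns):
        raise ValueError("ns must be sorted ascending")
    if any(not 1 <= n <= ds.n_meanings for n in ns):
        raise ValueError(f"each N must be in [1, {ds.n_meanings}]")
    rows = []
    for n in ns:
        sub = select_top_meanings(ds, n)
        row = {
            "N": n,
            "N_eff": effective_size(sub),
            "coverage": coverage(sub),
            "grf": np.nan,
            "gqd": np.nan,
        }
        try:
            dm = build_distance_matrix(sub, method=method, synonym_rule=synonym_rule)
            result = neighbor_joining(dm)
            report = score_inference(reference, result.tree)
            row["grf"] = report.grf
            row["gqd"] = report.gqd
        except (NoOverlapError, DegenerateNormalizerError):
            pass  # flagged by the NaN scores
        rows.append(row)
    return pd.DataFrame(rows, columns=["N", "N_eff", "coverage", "grf", "gqd"])
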