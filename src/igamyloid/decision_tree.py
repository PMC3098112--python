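"""Weighted decision-tree scoring of mutations with germline boosting.

Every mutation follows a three-edge path — region (CDR/FR), exposure
(exposed/buried), propensity shift (increase/decrease) — to one of eight
leaves; its score s is the product of the edge weights along the path.
Per germline, the leaf that best separates amyloidogenic from
non-amyloidogenic training derivatives is boosted tenfold and the worst
leaf decreased tenfold.  A sequence's amyloidogenic potential AM_seq is
the mean of its per-mutation scores, compared against a per-germline
threshold (AM_seq >= threshold -> AM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import yaml

from .alignment_io import AlignmentError, GermlineAlignment, SequenceRecord
from .bayes_classifier import EvaluationTable
from .mutation_model import (
    DEFAULT_SCALE,
    EdgeWeights,
    MutationRecord,
    MutationSet,
    PropensityScale,
    ShiftSummary,
    build_matrices_from_calls,
    call_mutations,
    derive_weights,
    summarize_shifts,
)

logger = logging.getLogger(__name__)

_SHIFT_ORDER = ("increase", "decrease")


@dataclass(frozen=True)
class Leaf:
    """One of the eight terminal nodes, identified by its path triple.

    Numbering convention: CDR before FR, exposed before buried, increase
    before decrease — leaf 1 = CDR/exposed/increase ... leaf 8 =
    FR/buried/decrease.
    """

    index: int
    region: str
    exposure: str
    shift: str

    @property
    def path(self) -> tuple[str, str, str]:
        return (self.region, self.exposure, self.shift)


LEAVES: tuple[Leaf, ...] = tuple(
    Leaf(
        index=1 + s + 2 * e + 4 * r,
        region=("CDR", "FR")[r],
        exposure=("exposed", "buried")[e],
        shift=_SHIFT_ORDER[s],
    )
    for r in range(2)
    for e in range(2)
    for s in range(2)
)
_LEAF_BY_PATH = {leaf.path: leaf for leaf in LEAVES}
_LEAF_BY_INDEX = {leaf.index: leaf for leaf in LEAVES}


def leaf_path(m: MutationRecord) -> Leaf:
    """Map a mutation's (region, exposure, shift) to its leaf."""
    return _LEAF_BY_PATH[(m.region, m.exposure, m.shift)]


@dataclass(frozen=True)
class BoostEntry:
    """Boosted/decreased leaf indices for one germline.

    Both indices ``None`` marks an explicit no-boost germline (no leaf pair
    separated its classes).
    """

    boosted_leaf: int | None
    decreased_leaf: int | None
    factor: float = 10.0

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError("boost factor must exceed 1")
        if (self.boosted_leaf is None) != (self.decreased_leaf is None):
            raise ValueError("boosted and decreased leaves must be set together")
        if self.boosted_leaf is not None and (
            self.boosted_leaf == self.decreased_leaf
        ):
            raise ValueError("boosted and decreased leaves must differ")


NO_BOOST = BoostEntry(boosted_leaf=None, decreased_leaf=None)


@dataclass
class TreeModel:
    """Edge weights, per-germline boost map and per-germline thresholds."""

    weights: EdgeWeights
    boost: dict[str, BoostEntry] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for gid in self.thresholds:
            if gid not in self.boost:
                raise ValueError(
                    f"germline {gid!r} has a threshold but no boost entry "
                    "(use an explicit no-boost entry)"
                )

    def threshold_for(self, germline_id: str) -> float:
        try:
            return self.thresholds[germline_id]
        except KeyError:
            raise KeyError(
                f"no threshold trained/published for germline {germline_id!r}"
            ) from None

    def boost_for(self, germline_id: str) -> BoostEntry:
        try:
            return self.boost[germline_id]
        except KeyError:
            raise KeyError(
                f"germline {germline_id!r} missing from the boost map; add an "
                "explicit no-boost entry if no path is boosted"
            ) from None

    # -- persistence (human-readable key-value model files) -------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "weights": dict(self.weights.weights),
            "provenance": dict(self.weights.provenance),
            "derived_values": dict(self.weights.derived_values),
            "boost": {
                gid: {
                    "boosted_leaf": e.boosted_leaf,
                    "decreased_leaf": e.decreased_leaf,
                    "factor": e.factor,
                }
                for gid, e in self.boost.items()
            },
            "thresholds": dict(self.thresholds),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Mapping) -> "TreeModel":
        weights = EdgeWeights(
            weights=dict(data["weights"]),
            provenance=dict(data.get("provenance", {})),
            derived_values=dict(data.get("derived_values", {})),
        )
        boost = {
            gid: BoostEntry(
                boosted_leaf=e.get("boosted_leaf"),
                decreased_leaf=e.get("decreased_leaf"),
                factor=e.get("factor", 10.0),
            )
            for gid, e in data.get("boost", {}).items()
        }
        return cls(
            weights=weights,
            boost=boost,
            thresholds=dict(data.get("thresholds", {})),
            version=data.get("version", "unversioned"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def mutation_score(
    m: MutationRecord, model: TreeModel, germline_id: str
) -> float:
    """Product of the three edge weights on the mutation's path, with the
    germline's boost factor applied at the leaf edge."""
    w = model.weights
    region_edge = m.region
    exposure_edge = f"{m.region}-{m.exposure}"
    leaf_edge = f"{m.region}-{m.exposure}-{m.shift}"
    s = w[region_edge] * w[exposure_edge] * w[leaf_edge]
    entry = model.boost_for(germline_id)
    if entry.boosted_leaf is not None:
        leaf = leaf_path(m)
        if leaf.index == entry.boosted_leaf:
            s *= entry.factor
        elif leaf.index == entry.decreased_leaf:
            s /= entry.factor
    return s


@dataclass(frozen=True)
class TreeScore:
    """Per-mutation scores, their mean AM_seq, and the thresholded label."""

    record_id: str
    germline_id: str
    scores: tuple[float, ...]
    threshold: float

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def am_seq(self) -> float:
        # A mutation-free sequence carries no amyloidogenic evidence.
        return sum(self.scores) / self.n if self.n else 0.0

    @property
    def label(self) -> str:
        if self.n == 0:
            return "NAM"
        return "AM" if self.am_seq >= self.threshold else "NAM"


def sequence_score(ms: MutationSet, model: TreeModel) -> TreeScore:
    """Score all mutations of a sequence and average them (AM_seq)."""
    threshold = model.threshold_for(ms.germline_id)
    scores = tuple(
        mutation_score(m, model, ms.germline_id) for m in ms.mutations
    )
    return TreeScore(
        record_id=ms.record_id,
        germline_id=ms.germline_id,
        scores=scores,
        threshold=threshold,
    )


@dataclass(frozen=True)
class LeafSeparation:
    """Per-leaf class separation for one germline.

    For each class, every sequence with >= 1 mutation contributes its
    fraction of mutations reaching each leaf; the separation at a leaf is
    the AM mean fraction minus the NAM mean fraction.  Fractions sum to 1
    per sequence, so separations sum to ~0 across the eight leaves.
    """

    germline_id: str
    separation: tuple[float, ...]  # indexed leaf 1..8 at [0..7]

    def __getitem__(self, leaf_index: int) -> float:
        return self.separation[leaf_index - 1]


def _mean_leaf_fractions(mutation_sets: Sequence[MutationSet]) -> list[float]:
    fractions = [0.0] * 8
    counted = 0
    for ms in mutation_sets:
        if not ms.mutations:
            continue
        counted += 1
        per_seq = [0.0] * 8
        for m in ms.mutations:
            per_seq[leaf_path(m).index - 1] += 1.0
        for i in range(8):
            fractions[i] += per_seq[i] / len(ms.mutations)
    if counted == 0:
        raise AlignmentError(
            "no sequence with mutations available for leaf fractions"
        )
    return [f / counted for f in fractions]


def compute_leaf_separation(
    aln: GermlineAlignment,
    model: TreeModel | None = None,
    scale: PropensityScale = DEFAULT_SCALE,
) -> LeafSeparation:
    """Per-leaf AM-minus-NAM mean leaf-usage fractions (boosts disabled).

    ``model`` is accepted for interface symmetry but only the propensity
    scale matters: separation drives boost selection, so it is defined on
    the unboosted tree.
    """
    am = [call_mutations(r, aln, scale) for r in aln.members("AM")]
    nam = [call_mutations(r, aln, scale) for r in aln.members("NAM")]
    if not am or not nam:
        raise AlignmentError(
            f"germline {aln.germline_id!r}: both classes must be nonempty "
            "to compute leaf separation"
        )
    am_frac = _mean_leaf_fractions(am)
    nam_frac = _mean_leaf_fractions(nam)
    return LeafSeparation(
        germline_id=aln.germline_id,
        separation=tuple(a - b for a, b in zip(am_frac, nam_frac)),
    )


def select_boost(
    sep: LeafSeparation | Sequence[float],
    germline_id: str = "",
    factor: float = 10.0,
) -> BoostEntry:
    """Pick the boosted (max separation) and decreased (min) leaves.

    Ties break toward the lower leaf index; a flat separation profile
    yields the explicit no-boost entry.
    """
    values = (
        sep.separation if isinstance(sep, LeafSeparation) else tuple(sep)
    )
    if len(values) != 8:
        raise ValueError("expected separations for exactly 8 leaves")
    if len(set(values)) == 1:
        return BoostEntry(None, None, factor=factor)
    best = max(range(8), key=lambda i: (values[i], -i))
    worst = min(range(8), key=lambda i: (values[i], i))
    return BoostEntry(boosted_leaf=best + 1, decreased_leaf=worst + 1, factor=factor)


class ThresholdResult(NamedTuple):
    threshold: float
    balanced_accuracy: float


def choose_threshold(
    am_scores: Sequence[float], nam_scores: Sequence[float]
) -> ThresholdResult:
    """Threshold maximizing balanced training accuracy (AM_seq >= t -> AM).

    Candidate cuts are midpoints of adjacent sorted pooled scores; among
    equally accurate candidates the returned threshold is the midpoint
    between the highest correctly-excluded NAM score and the lowest
    correctly-included AM score.
    """
    if not am_scores or not nam_scores:
        raise ValueError("both score lists must be nonempty")
    am = sorted(am_scores)
    nam = sorted(nam_scores)
    pooled = sorted(list(am) + list(nam))
    candidates = sorted(
        {(a + b) / 2.0 for a, b in zip(pooled, pooled[1:])} or {pooled[0]}
    )

    def balanced(t: float) -> float:
        tpr = sum(s >= t for s in am) / len(am)
        tnr = sum(s < t for s in nam) / len(nam)
        return (tpr + tnr) / 2.0

    best_acc = max(balanced(t) for t in candidates)
    ties = [t for t in candidates if balanced(t) == best_acc]
    for t in ties:
        excluded_nam = [s for s in nam if s < t]
        included_am = [s for s in am if s >= t]
        if excluded_nam and included_am:
            refined = (max(excluded_nam) + min(included_am)) / 2.0
            if balanced(refined) == best_acc:
                return ThresholdResult(refined, best_acc)
    return ThresholdResult(ties[0], best_acc)


def tree_classify(
    record: SequenceRecord,
    aln: GermlineAlignment,
    model: TreeModel,
    scale: PropensityScale = DEFAULT_SCALE,
) -> TreeScore:
    """Call mutations against the germline and score them through the tree."""
    ms = call_mutations(record, aln, scale)
    return sequence_score(ms, model)


def tree_evaluate(
    alns: GermlineAlignment | Iterable[GermlineAlignment] | Mapping[str, GermlineAlignment],
    test: Iterable[SequenceRecord],
    model: TreeModel,
    scale: PropensityScale = DEFAULT_SCALE,
) -> EvaluationTable:
    """Classify a labelled set through the tree and tally per-germline C/A."""
    if isinstance(alns, GermlineAlignment):
        by_id = {alns.germline_id: alns}
    elif isinstance(alns, Mapping):
        by_id = dict(alns)
    else:
        by_id = {a.germline_id: a for a in alns}
    table = EvaluationTable()
    for rec in test:
        if rec.label not in ("AM", "NAM"):
            continue
        if rec.germline_id not in by_id:
            logger.warning(
                "tree evaluate: record %s has unknown germline %r; excluded",
                rec.id,
                rec.germline_id,
            )
            continue
        score = tree_classify(rec, by_id[rec.germline_id], model, scale)
        table.add(rec.germline_id, rec.label, score.label == rec.label)
    return table


def train_tree(
    alignments: GermlineAlignment | Iterable[GermlineAlignment],
    scale: PropensityScale = DEFAULT_SCALE,
    boost_factor: float = 10.0,
    version: str = "trained",
) -> TreeModel:
    """Train a tree model from labelled germline alignments.

    Edge weights derive from the pooled AM-exclusive shift counts across
    all alignments (ratio-to-max); boosts and thresholds are germline
    specific, with thresholds chosen on the boosted training scores.
    """
    alns = (
        [alignments]
        if isinstance(alignments, GermlineAlignment)
        else list(alignments)
    )
    if not alns:
        raise ValueError("no alignments supplied")

    labelled_calls = [
        (call_mutations(rec, aln, scale), rec.label)
        for aln in alns
        for rec in aln.derivatives
        if rec.label in ("AM", "NAM")
    ]
    matrices = build_matrices_from_calls(labelled_calls, scale)
    summary: ShiftSummary = summarize_shifts(matrices)
    # sparse training data may leave a sibling pair without exclusive
    # mutations; such pairs carry no evidence and stay neutrally weighted
    weights = derive_weights(summary, zero_pair="neutral")

    model = TreeModel(weights=weights, version=version)
    for aln in alns:
        sep = compute_leaf_separation(aln, scale=scale)
        entry = select_boost(sep, aln.germline_id, factor=boost_factor)
        model.boost[aln.germline_id] = entry
        # Threshold on boosted training scores: put a provisional threshold
        # in place so sequence_score can run, then replace it.
        model.thresholds[aln.germline_id] = 0.0
        am_scores = [
            sequence_score(call_mutations(r, aln, scale), model).am_seq
            for r in aln.members("AM")
        ]
        nam_scores = [
            sequence_score(call_mutations(r, aln, scale), model).am_seq
            for r in aln.members("NAM")
        ]
        model.thresholds[aln.germline_id] = choose_threshold(
            am_scores, nam_scores
        ).threshold
    return model
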