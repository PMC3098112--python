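"""Mutation calling, positional profiles, propensity-ordered matrices.

Somatic mutations are called per alignment column against the germline.
Each mutation is annotated with its structural stratum (CDR/FR x
exposed/buried) and with the direction of the change in beta-sheet-forming
propensity it causes, using a per-residue ddG scale (kcal/mol; more positive
= stronger sheet former).  From the called mutations this module builds:

* per-position, per-class (AM/NAM) Laplace-corrected mutation probabilities
  p = (k + 1) / (n + 2), the parameters of the naive Bayes classifier;
* 20x20 mutation-count matrices per stratum with both axes in increasing
  propensity order, so that any cell strictly right of the diagonal is a
  propensity-increasing substitution;
* difference and AM-exclusive variants of those matrices, the
  increase/decrease shift summary over the exclusive cells, and
  ratio-to-max decision-tree edge weights derived from that summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignment_io import (
    GAP,
    AlignmentError,
    GermlineAlignment,
    SequenceRecord,
)

# Beta-sheet-forming propensities, ddG in kcal/mol.  Proline's literature
# value is an inequality (< -3); it is stored as -3.0, which preserves its
# rank as the weakest sheet former (only ordering enters shift calls).
SHEET_PROPENSITY_KCAL_MOL: dict[str, float] = {
    "T": 1.1,
    "I": 1.0,
    "Y": 0.96,
    "F": 0.86,
    "V": 0.82,
    "M": 0.72,
    "S": 0.70,
    "W": 0.54,
    "C": 0.52,
    "L": 0.51,
    "R": 0.45,
    "K": 0.27,
    "Q": 0.23,
    "E": 0.01,
    "A": 0.00,
    "H": -0.02,
    "N": -0.08,
    "D": -0.94,
    "G": -1.2,
    "P": -3.0,
}

STRATA = (
    ("CDR", "exposed"),
    ("CDR", "buried"),
    ("FR", "exposed"),
    ("FR", "buried"),
)


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (matching printed-table conventions)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class PropensityScale:
    """A per-residue sheet-propensity scale and its induced residue order."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError("propensity scale must cover exactly 20 residues")
        vals = list(self.values.values())
        if len(set(vals)) != 20:
            raise ValueError("propensity values must be distinct")

    @property
    def order(self) -> tuple[str, ...]:
        """The 20 residues sorted by increasing propensity."""
        return tuple(sorted(self.values, key=self.values.__getitem__))

    def rank(self, residue: str) -> int:
        return self.order.index(residue)

    def shift(self, from_res: str, to_res: str) -> str:
        """'increase' if the replacement is a stronger sheet former."""
        if self.values[to_res] > self.values[from_res]:
            return "increase"
        return "decrease"

    @classmethod
    def default(cls) -> "PropensityScale":
        return cls(dict(SHEET_PROPENSITY_KCAL_MOL))


DEFAULT_SCALE = PropensityScale.default()


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation: column, residues, stratum and propensity shift."""

    position: int
    from_res: str
    to_res: str
    region: str
    exposure: str
    shift: str

    def __post_init__(self) -> None:
        if self.from_res == self.to_res:
            raise ValueError("a mutation must change the residue")
        if GAP in (self.from_res, self.to_res):
            raise ValueError("gap columns are not mutations")

    @property
    def stratum(self) -> tuple[str, str]:
        return (self.region, self.exposure)


@dataclass(frozen=True)
class MutationSet:
    """All mutations of one derivative, plus the mutated-position set M."""

    record_id: str
    germline_id: str
    mutations: tuple[MutationRecord, ...]

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)


def call_mutations(
    record: SequenceRecord,
    aln: GermlineAlignment,
    scale: PropensityScale = DEFAULT_SCALE,
) -> MutationSet:
    """Call mutations of ``record`` against the germline of ``aln``.

    A mutation is a residue differing from the germline at an unmasked
    column where neither sequence has a gap.  Gap columns are silently
    excluded; masked leading columns never contribute.
    """
    if len(record) != aln.length:
        raise AlignmentError(
            f"record {record.id!r} has length {len(record)}, "
            f"alignment length is {aln.length}"
        )
    muts = []
    for pos in aln.analysis_range:
        g = aln.germline_seq[pos - 1]
        d = record.sequence[pos - 1]
        if g == d or GAP in (g, d):
            continue
        ann = aln.annotation_at(pos)
        muts.append(
            MutationRecord(
                position=pos,
                from_res=g,
                to_res=d,
                region=ann.region,
                exposure=ann.exposure,
                shift=scale.shift(g, d),
            )
        )
    return MutationSet(
        record_id=record.id,
        germline_id=aln.germline_id,
        mutations=tuple(muts),
    )


def mutated_positions(
    record: SequenceRecord, aln: GermlineAlignment
) -> frozenset[int]:
    """Mutated-position set M without stratum annotation (profile counting)."""
    out = set()
    for pos in aln.analysis_range:
        g = aln.germline_seq[pos - 1]
        d = record.sequence[pos - 1]
        if g != d and GAP not in (g, d):
            out.add(pos)
    return frozenset(out)


@dataclass(frozen=True)
class PositionalProfile:
    """Laplace-corrected per-position mutation probabilities per class.

    For class size n and k members mutated at column x,
    p(x) = (k + 1) / (n + 2) and q(x) = 1 - p(x); the correction keeps
    every probability strictly inside (0, 1).
    """

    germline_id: str
    positions: tuple[int, ...]
    p_am: Mapping[int, float]
    p_nam: Mapping[int, float]
    n_am: int
    n_nam: int

    def q_am(self, x: int) -> float:
        return 1.0 - self.p_am[x]

    def q_nam(self, x: int) -> float:
        return 1.0 - self.p_nam[x]


def estimate_profile(
    aln: GermlineAlignment,
    *,
    exclude_id: str | None = None,
    exclude_from: str | None = None,
) -> PositionalProfile:
    """Estimate the positional profile from the alignment's labelled members.

    ``exclude_id``/``exclude_from`` drop one record from one class only —
    the leave-one-out primitive (the other class's profile is untouched).
    """
    members = {"AM": list(aln.members("AM")), "NAM": list(aln.members("NAM"))}
    if exclude_id is not None and exclude_from is not None:
        members[exclude_from] = [
            r for r in members[exclude_from] if r.id != exclude_id
        ]
    for cls in ("AM", "NAM"):
        if not members[cls]:
            raise AlignmentError(
                f"germline {aln.germline_id!r}: cannot estimate a profile "
                f"with an empty {cls} class"
            )

    positions = tuple(aln.analysis_range)
    counts = {cls: dict.fromkeys(positions, 0) for cls in ("AM", "NAM")}
    for cls, recs in members.items():
        for rec in recs:
            for pos in mutated_positions(rec, aln):
                counts[cls][pos] += 1

    n_am, n_nam = len(members["AM"]), len(members["NAM"])
    p_am = {x: (counts["AM"][x] + 1) / (n_am + 2) for x in positions}
    p_nam = {x: (counts["NAM"][x] + 1) / (n_nam + 2) for x in positions}
    return PositionalProfile(
        germline_id=aln.germline_id,
        positions=positions,
        p_am=p_am,
        p_nam=p_nam,
        n_am=n_am,
        n_nam=n_nam,
    )


@dataclass
class MutationMatrixSet:
    """Per-stratum 20x20 mutation-count matrices in propensity order.

    Rows are original residues, columns replacements; both axes run in
    increasing sheet propensity so cells strictly right of the diagonal are
    propensity increases.  ``difference`` is the per-class-normalized
    am - nam matrix (each class divided by its total mutation count);
    ``exclusive`` is the binary matrix of substitution types seen in AM
    derivatives and never in NAM derivatives.
    """

    scale: PropensityScale
    am_counts: dict[tuple[str, str], np.ndarray]
    nam_counts: dict[tuple[str, str], np.ndarray]
    difference: dict[tuple[str, str], np.ndarray] = field(init=False)
    exclusive: dict[tuple[str, str], np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        am_total = sum(int(m.sum()) for m in self.am_counts.values())
        nam_total = sum(int(m.sum()) for m in self.nam_counts.values())
        self.difference = {}
        self.exclusive = {}
        for stratum in STRATA:
            am = self.am_counts[stratum].astype(float)
            nam = self.nam_counts[stratum].astype(float)
            am_n = am / am_total if am_total else am
            nam_n = nam / nam_total if nam_total else nam
            self.difference[stratum] = am_n - nam_n
            self.exclusive[stratum] = (
                (self.am_counts[stratum] > 0) & (self.nam_counts[stratum] == 0)
            ).astype(int)

    def to_frame(self, kind: str, stratum: tuple[str, str]) -> pd.DataFrame:
        """Export one matrix as a labelled DataFrame (propensity order)."""
        mat = getattr(self, kind)[stratum]
        order = list(self.scale.order)
        return pd.DataFrame(mat, index=order, columns=order)


def build_matrices(
    aln_or_mutations: GermlineAlignment | Iterable[MutationSet],
    scale: PropensityScale = DEFAULT_SCALE,
) -> MutationMatrixSet:
    """Build per-stratum AM/NAM mutation matrices.

    Accepts either a labelled alignment (mutations are called internally)
    or pre-called :class:`MutationSet` objects paired with labels via the
    alignment — when passing mutation sets use :func:`build_matrices_from_calls`.
    """
    if isinstance(aln_or_mutations, GermlineAlignment):
        aln = aln_or_mutations
        calls = [
            (call_mutations(rec, aln, scale), rec.label)
            for rec in aln.derivatives
            if rec.label in ("AM", "NAM")
        ]
    else:
        raise TypeError(
            "build_matrices expects a GermlineAlignment; use "
            "build_matrices_from_calls for pre-called mutation sets"
        )
    return build_matrices_from_calls(calls, scale)


def build_matrices_from_calls(
    labelled_calls: Iterable[tuple[MutationSet, str]],
    scale: PropensityScale = DEFAULT_SCALE,
) -> MutationMatrixSet:
    order = scale.order
    idx = {res: i for i, res in enumerate(order)}
    am = {s: np.zeros((20, 20), dtype=int) for s in STRATA}
    nam = {s: np.zeros((20, 20), dtype=int) for s in STRATA}
    for ms, label in labelled_calls:
        if label not in ("AM", "NAM"):
            continue
        target = am if label == "AM" else nam
        for m in ms.mutations:
            target[m.stratum][idx[m.from_res], idx[m.to_res]] += 1
    return MutationMatrixSet(scale=scale, am_counts=am, nam_counts=nam)


@dataclass(frozen=True)
class ShiftSummary:
    """Increase/decrease counts of AM-exclusive substitution types.

    Each exclusive cell (a substitution *type*, not its multiplicity)
    contributes one count to its stratum, on the increase side if the cell
    lies right of the diagonal in propensity order.
    """

    counts: Mapping[tuple[str, str], tuple[int, int]]  # stratum -> (inc, dec)

    def increase(self, stratum: tuple[str, str]) -> int:
        return self.counts[stratum][0]

    def decrease(self, stratum: tuple[str, str]) -> int:
        return self.counts[stratum][1]

    def stratum_total(self, stratum: tuple[str, str]) -> int:
        inc, dec = self.counts[stratum]
        return inc + dec

    def region_total(self, region: str) -> int:
        return sum(
            self.stratum_total(s) for s in STRATA if s[0] == region
        )

    def exposure_total(self, exposure: str) -> int:
        return sum(
            self.stratum_total(s) for s in STRATA if s[1] == exposure
        )

    def percent_increase(self, stratum: tuple[str, str]) -> int | None:
        """Percent of exclusive cells that increase propensity (nearest int).

        ``None`` for an empty stratum (the percentage is undefined).
        """
        total = self.stratum_total(stratum)
        if total == 0:
            return None
        return int(_round0(100.0 * self.increase(stratum) / total))

    def percent_decrease(self, stratum: tuple[str, str]) -> int | None:
        total = self.stratum_total(stratum)
        if total == 0:
            return None
        return int(_round0(100.0 * self.decrease(stratum) / total))

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str], tuple[int, int]]
    ) -> "ShiftSummary":
        """Build directly from per-stratum (increase, decrease) counts."""
        return cls(counts={s: tuple(counts[s]) for s in STRATA})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (region, exposure), (inc, dec) in self.counts.items():
            rows.append(
                {
                    "region": region,
                    "exposure": exposure,
                    "increase": inc,
                    "decrease": dec,
                    "percent_increase": self.percent_increase((region, exposure)),
                }
            )
        return pd.DataFrame(rows)


def _round0(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1"), ROUND_HALF_UP))


def summarize_shifts(mm: MutationMatrixSet) -> ShiftSummary:
    """Count increase/decrease exclusive cells per stratum.

    Cells above (right of) the diagonal are increases because both axes run
    in increasing propensity order.
    """
    counts = {}
    for stratum in STRATA:
        ex = mm.exclusive[stratum]
        inc = int(np.triu(ex, k=1).sum())
        dec = int(np.tril(ex, k=-1).sum())
        counts[stratum] = (inc, dec)
    return ShiftSummary(counts=counts)


# Decision-tree edge names.  Sibling pairs share a parent node; under the
# ratio-to-max convention the larger-count sibling carries weight 1.0 and
# the smaller carries smaller/larger (2 decimals).
EDGE_NAMES = (
    "CDR",
    "FR",
    "CDR-exposed",
    "CDR-buried",
    "FR-exposed",
    "FR-buried",
    "CDR-exposed-increase",
    "CDR-exposed-decrease",
    "CDR-buried-increase",
    "CDR-buried-decrease",
    "FR-exposed-increase",
    "FR-exposed-decrease",
    "FR-buried-increase",
    "FR-buried-decrease",
)

_SIBLING_PAIRS: tuple[tuple[str, str], ...] = (
    ("CDR", "FR"),
    ("CDR-exposed", "CDR-buried"),
    ("FR-exposed", "FR-buried"),
    ("CDR-exposed-increase", "CDR-exposed-decrease"),
    ("CDR-buried-increase", "CDR-buried-decrease"),
    ("FR-exposed-increase", "FR-exposed-decrease"),
    ("FR-buried-increase", "FR-buried-decrease"),
)


@dataclass(frozen=True)
class EdgeWeights:
    """Weights for the 14 decision-tree edges with per-edge provenance.

    ``provenance[edge]`` is ``"derived"`` when the weight follows the
    ratio-to-max convention from shift counts, or ``"published"`` when it
    was taken from the published table; in the latter case the
    convention-derived value is kept in ``derived_values``.
    """

    weights: Mapping[str, float]
    provenance: Mapping[str, str]
    derived_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(EDGE_NAMES) - set(self.weights)
        if missing:
            raise ValueError(f"missing edge weights: {sorted(missing)}")
        for edge, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"edge {edge!r} has non-positive weight {w}")

    def __getitem__(self, edge: str) -> float:
        return self.weights[edge]


def _pair_counts(summary: ShiftSummary, a: str, b: str) -> tuple[int, int]:
    def count(edge: str) -> int:
        parts = edge.split("-")
        if len(parts) == 1:  # region edge
            return summary.region_total(parts[0])
        if len(parts) == 2:  # region-exposure edge
            return summary.stratum_total((parts[0], parts[1]))
        stratum = (parts[0], parts[1])
        return (
            summary.increase(stratum)
            if parts[2] == "increase"
            else summary.decrease(stratum)
        )

    return count(a), count(b)


def derive_weights(
    summary: ShiftSummary,
    convention: str = "ratio_to_max",
    published: Mapping[str, float] | None = None,
    zero_pair: str = "error",
) -> EdgeWeights:
    """Derive tree edge weights from a shift summary (ratio-to-max).

    Within each sibling pair the larger count maps to 1.0 and the smaller
    to smaller/larger, rounded half-up to 2 decimals.  If ``published``
    maps edges to published weights, any sibling pair whose derived values
    disagree with the published ones is populated from the published table
    (provenance ``"published"``) and the derived values are retained in
    ``derived_values``.
    """
    if convention != "ratio_to_max":
        raise ValueError(f"unknown convention {convention!r}")
    weights: dict[str, float] = {}
    provenance: dict[str, str] = {}
    derived_meta: dict[str, float] = {}
    for a, b in _SIBLING_PAIRS:
        ca, cb = _pair_counts(summary, a, b)
        larger = max(ca, cb)
        if larger == 0:
            if zero_pair == "neutral":
                # no evidence in this pair: both siblings weighted equally
                wa = wb = 1.0
            else:
                raise ValueError(
                    f"cannot derive weights for pair ({a}, {b}): zero counts"
                )
        else:
            # floor at 0.01 keeps weights positive when the smaller count
            # is zero (or the ratio rounds to 0.00)
            wa = 1.0 if ca >= cb else max(_round2(ca / cb), 0.01)
            wb = 1.0 if cb > ca else max(_round2(cb / ca), 0.01)
        derived = {a: wa, b: wb}
        if published is not None and (
            published.get(a) != wa or published.get(b) != wb
        ):
            for e in (a, b):
                weights[e] = published[e]
                provenance[e] = "published"
                derived_meta[e] = derived[e]
        else:
            for e in (a, b):
                weights[e] = derived[e]
                provenance[e] = "derived"
    return EdgeWeights(
        weights=weights, provenance=provenance, derived_values=derived_meta
    )


def matrix_to_tsv(mm: MutationMatrixSet, kind: str, stratum: tuple[str, str]) -> str:
    """Serialize one matrix as a tab-separated table with propensity-order
    header row/column."""
    return mm.to_frame(kind, stratum).to_csv(sep="\t")


def plot_matrix(mm: MutationMatrixSet, kind: str, stratum: tuple[str, str], ax=None):
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib.pyplot as plt

    frame = mm.to_frame(kind, stratum)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(frame.values, cmap="viridis")
    ax.set_xticks(range(20), frame.columns)
    ax.set_yticks(range(20), frame.index)
    ax.set_xlabel("replacement residue (increasing sheet propensity)")
    ax.set_ylabel("original residue")
    ax.set_title(f"{kind} {stratum[1]} {stratum[0]}")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
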