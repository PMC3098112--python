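"""Seeded germline-derivative fixtures with plantable amyloid signatures.

The generator emulates the data structure the classifiers assume: a single
germline, derivative sequences whose mutations fall into class-specific
position sets, and per-column region/exposure annotations.  Amyloidogenic
(AM) members mutate preferentially at their signature columns with
replacements biased toward increased beta-sheet propensity; non-amyloidogenic
(NAM) members carry an analogous signature at disjoint columns without the
propensity bias.  All randomness flows through one numpy Generator
(PCG64) seeded explicitly, so a (spec, seed) pair regenerates byte-identical
fixture files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import (
    AMINO_ACIDS,
    GermlineAlignment,
    ResidueAnnotation,
    SequenceRecord,
    write_alignment,
)
from .mutation_model import DEFAULT_SCALE, PropensityScale, STRATA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSpec:
    """Where and how strongly class-specific mutation signal is planted.

    ``am_positions`` / ``nam_positions`` are disjoint 1-based columns that
    carry the class signatures.  Each class member mutates at each of its
    signature columns with probability ``hit_prob``; every other column
    mutates with ``background_prob``.  An AM signature mutation increases
    sheet propensity with probability ``am_shift_bias`` (replacement drawn
    uniformly from the residues strictly above the germline residue in
    propensity order).  ``strata`` optionally pins signature columns to a
    (region, exposure) stratum; unpinned columns cycle through the four
    strata deterministically.
    """

    am_positions: frozenset[int]
    nam_positions: frozenset[int]
    hit_prob: float = 0.9
    background_prob: float = 0.02
    am_shift_bias: float = 0.9
    strata: Mapping[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "am_positions", frozenset(self.am_positions))
        object.__setattr__(self, "nam_positions", frozenset(self.nam_positions))
        if self.am_positions & self.nam_positions:
            raise ValueError("AM and NAM signature positions must be disjoint")
        for name in ("hit_prob", "background_prob", "am_shift_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def validate_for_length(self, length: int, mask_prefix: int) -> None:
        for pos in self.am_positions | self.nam_positions:
            if not mask_prefix < pos <= length:
                raise ValueError(
                    f"signature column {pos} outside the analysis range "
                    f"({mask_prefix + 1}..{length})"
                )


@dataclass(frozen=True)
class FixtureBundle:
    """A generated train alignment plus labelled holdout records."""

    train: GermlineAlignment
    holdout: tuple[SequenceRecord, ...]
    spec: SignatureSpec
    seed: int
    generator_algorithm: str = "numpy.random.PCG64"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA, annotation and label files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "train_fasta": out / "train.fasta",
            "annotations": out / "annotations.tsv",
            "labels": out / "labels.tsv",
            "holdout_fasta": out / "holdout.fasta",
        }
        write_alignment(
            self.train,
            paths["train_fasta"],
            paths["annotations"],
            paths["labels"],
        )
        from .alignment_io import records_to_fasta_str

        paths["holdout_fasta"].write_text(records_to_fasta_str(self.holdout))
        with open(paths["labels"], "a", newline="") as fh:
            for rec in self.holdout:
                fh.write(f"{rec.id}\t{rec.label}\n")
        return paths


def generate_germline(length: int, seed: int) -> str:
    """Uniform random 20-letter germline sequence of the given length."""
    if length < 6:
        raise ValueError(
            f"germline length must be >= 6 (a 5-column mask must leave "
            f"analysable columns), got {length}"
        )
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(letters, size=length))


def _biased_replacement(
    rng: np.random.Generator,
    original: str,
    want_increase: bool,
    scale: PropensityScale,
) -> str:
    """Replacement drawn uniformly from residues strictly above (below) the
    original in propensity order; falls back to the achievable direction."""
    order = scale.order
    rank = scale.rank(original)
    pool = order[rank + 1 :] if want_increase else order[:rank]
    if not pool:
        direction = "increase" if want_increase else "decrease"
        logger.info(
            "shift bias infeasible for %s (no %s available); using the "
            "opposite direction",
            original,
            direction,
        )
        pool = order[:rank] if want_increase else order[rank + 1 :]
    return str(rng.choice(list(pool)))


def _uniform_replacement(rng: np.random.Generator, original: str) -> str:
    pool = [a for a in AMINO_ACIDS if a != original]
    return str(rng.choice(pool))


def _default_annotations(
    length: int, spec: SignatureSpec
) -> tuple[ResidueAnnotation, ...]:
    anns = []
    for pos in range(1, length + 1):
        if pos in spec.strata:
            region, exposure = spec.strata[pos]
        else:
            region, exposure = STRATA[(pos - 1) % len(STRATA)]
        anns.append(ResidueAnnotation(pos, region, exposure))
    return tuple(anns)


def _mutate(
    rng: np.random.Generator,
    germline: str,
    spec: SignatureSpec,
    label: str,
    mask_prefix: int,
    scale: PropensityScale,
) -> str:
    sig = spec.am_positions if label == "AM" else spec.nam_positions
    seq = list(germline)
    for pos in range(mask_prefix + 1, len(germline) + 1):
        original = germline[pos - 1]
        if pos in sig:
            if rng.random() < spec.hit_prob:
                if label == "AM":
                    want_up = rng.random() < spec.am_shift_bias
                    seq[pos - 1] = _biased_replacement(
                        rng, original, want_up, scale
                    )
                else:
                    seq[pos - 1] = _uniform_replacement(rng, original)
        elif pos not in spec.am_positions | spec.nam_positions:
            if rng.random() < spec.background_prob:
                seq[pos - 1] = _uniform_replacement(rng, original)
    return "".join(seq)


def generate_derivatives(
    germline: str,
    spec: SignatureSpec,
    n_am: int,
    n_nam: int,
    seed: int,
    *,
    n_am_holdout: int = 0,
    n_nam_holdout: int = 0,
    germline_id: str = "SYNTH",
    mask_prefix: int = 5,
    scale: PropensityScale = DEFAULT_SCALE,
) -> FixtureBundle:
    """Generate labelled training derivatives (and optional holdout records).

    One PCG64 stream seeded with ``seed`` drives every draw, so the bundle
    (including its serialized files) is reproducible from (spec, seed).
    """
    spec.validate_for_length(len(germline), mask_prefix)
    rng = np.random.default_rng(seed)

    def make(label: str, split: str, count: int, offset: int = 0):
        recs = []
        for i in range(count):
            seq = _mutate(rng, germline, spec, label, mask_prefix, scale)
            recs.append(
                SequenceRecord(
                    id=f"{germline_id}_{split}_{label}_{i + offset:03d}",
                    sequence=seq,
                    label=label,
                    germline_id=germline_id,
                )
            )
        return recs

    train_records = make("AM", "train", n_am) + make("NAM", "train", n_nam)
    holdout_records = make("AM", "test", n_am_holdout) + make(
        "NAM", "test", n_nam_holdout
    )

    train = GermlineAlignment(
        germline_id=germline_id,
        germline_seq=germline,
        derivatives=tuple(train_records),
        annotations=_default_annotations(len(germline), spec),
        mask_prefix=mask_prefix,
    )
    return FixtureBundle(
        train=train,
        holdout=tuple(holdout_records),
        spec=spec,
        seed=seed,
    )


def default_signature_spec(
    length: int,
    mask_prefix: int = 5,
    n_signature: int = 8,
    hit_prob: float = 0.9,
    background_prob: float = 0.02,
    am_shift_bias: float = 0.9,
) -> SignatureSpec:
    """Evenly spaced, interleaved AM/NAM signature columns over the range."""
    usable = list(range(mask_prefix + 1, length + 1))
    if len(usable) < 2 * n_signature:
        raise ValueError("sequence too short for the requested signature size")
    step = len(usable) // (2 * n_signature)
    chosen = [usable[i * step] for i in range(2 * n_signature)]
    return SignatureSpec(
        am_positions=frozenset(chosen[0::2]),
        nam_positions=frozenset(chosen[1::2]),
        hit_prob=hit_prob,
        background_prob=background_prob,
        am_shift_bias=am_shift_bias,
    )
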