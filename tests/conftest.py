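"""Shared builders for tiny, fully specified alignment fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from igamyloid.alignment_io import (
    GermlineAlignment,
    ResidueAnnotation,
    SequenceRecord,
)
from igamyloid.mutation_model import STRATA


def annotations_for(length, strata=None, default=("FR", "buried")):
    """Full annotation table; ``strata`` pins columns to (region, exposure)."""
    strata = strata or {}
    return tuple(
        ResidueAnnotation(pos, *strata.get(pos, default))
        for pos in range(1, length + 1)
    )


def cycled_annotations(length):
    """Annotations cycling through the four strata."""
    return tuple(
        ResidueAnnotation(pos, *STRATA[(pos - 1) % 4])
        for pos in range(1, length + 1)
    )


def make_alignment(
    germline,
    derivatives,
    mask=0,
    strata=None,
    default_stratum=("FR", "buried"),
    germline_id="G1",
):
    """Build a GermlineAlignment from (id, seq, label) triples."""
    records = tuple(
        SequenceRecord(id=i, sequence=s, label=lab, germline_id=germline_id)
        for i, s, lab in derivatives
    )
    return GermlineAlignment(
        germline_id=germline_id,
        germline_seq=germline,
        derivatives=records,
        annotations=annotations_for(len(germline), strata, default_stratum),
        mask_prefix=mask,
    )


def random_alignment(rng, n_am=3, n_nam=3, length=10, mutation_prob=0.3,
                     mask=0, germline_id="G1"):
    """Random small alignment for oracle/property tests (no gaps)."""
    from igamyloid.alignment_io import AMINO_ACIDS

    letters = list(AMINO_ACIDS)
    germline = "".join(rng.choice(letters, size=length))
    derivs = []
    for cls, n in (("AM", n_am), ("NAM", n_nam)):
        for i in range(n):
            seq = list(germline)
            for pos in range(length):
                if rng.random() < mutation_prob:
                    pool = [a for a in letters if a != germline[pos]]
                    seq[pos] = rng.choice(pool)
            derivs.append((f"{cls}{i}", "".join(seq), cls))
    return make_alignment(germline, derivs, mask=mask, germline_id=germline_id,
                          strata={p: STRATA[(p - 1) % 4]
                                  for p in range(1, length + 1)})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
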