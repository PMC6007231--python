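from __future__ import annotations

import numpy as np
import pytest

from tgeclass.homology import PairwiseAlignment, load_matrix
from tgeclass.variation import compute_midline

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum80():
    return load_matrix("BLOSUM80")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230923)


def random_gapped_alignment(rng, matrix, min_cols=20, max_cols=60):
    """Random local-alignment object with gaps but no gap-gap columns."""
    n_cols = int(rng.integers(min_cols, max_cols + 1))
    q_chars, s_chars = [], []
    # never start or end with a gap (local alignments are flush)
    cats = ["="]
    for _ in range(n_cols - 2):
        cats.append(str(rng.choice(["=", "=", "=", "S", "D", "I"])))
    cats.append("=")
    for cat in cats:
        if cat == "D":
            q_chars.append("-")
            s_chars.append(str(rng.choice(list(AA20))))
        elif cat == "I":
            q_chars.append(str(rng.choice(list(AA20))))
            s_chars.append("-")
        elif cat == "S":
            x = str(rng.choice(list(AA20)))
            y = str(rng.choice([a for a in AA20 if a != x]))
            q_chars.append(x)
            s_chars.append(y)
        else:
            x = str(rng.choice(list(AA20)))
            q_chars.append(x)
            s_chars.append(x)
    q_aln = "".join(q_chars)
    s_aln = "".join(s_chars)
    q_start = int(rng.integers(1, 6))
    s_start = int(rng.integers(1, 6))
    q_res = sum(c != "-" for c in q_aln)
    s_res = sum(c != "-" for c in s_aln)
    return PairwiseAlignment(
        query_id="q", subject_id="s", e_value=1e-40, bit_score=100.0,
        q_start=q_start, q_end=q_start + q_res - 1,
        s_start=s_start, s_end=s_start + s_res - 1,
        q_aln=q_aln, s_aln=s_aln,
        midline=compute_midline(q_aln, s_aln, matrix),
    )
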