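"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: the aligner oracle is a
plain Gotoh dynamic program, the digestion oracle enumerates cleavage-site
pairs directly, and the event oracle labels alignment columns one by one
before grouping.
"""

from __future__ import annotations

import re


def gotoh_local_score(a: str, b: str, matrix, gap_open: int = 10, gap_extend: int = 1) -> float:
    """Optimal local affine-gap alignment score; a gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    first = gap_open + gap_extend  # cost of opening a gap of length 1
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consuming b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_tryptic_peptides(
    sequence: str,
    missed_cleavages: int,
    min_len: int = 1,
    max_len: int | None = None,
    kp_suppression: bool = True,
) -> list[tuple[str, int, int]]:
    """All tryptic peptides by direct cleavage-site enumeration.

    Cleavage sites are the positions after K/R (not before P when
    suppression is on); a peptide is any stretch between two sites
    spanning at most ``missed_cleavages`` internal sites.
    """
    n = len(sequence)
    sites = [0]
    for i in range(n - 1):
        if sequence[i] in "KR" and not (kp_suppression and sequence[i + 1] == "P"):
            sites.append(i + 1)
    sites.append(n)
    out = []
    for si in range(len(sites) - 1):
        for sj in range(si + 1, len(sites)):
            if sj - si - 1 > missed_cleavages:
                break
            start, end = sites[si], sites[sj]
            if end == start:
                continue
            pep = sequence[start:end]
            if len(pep) < min_len:
                continue
            if max_len is not None and len(pep) > max_len:
                continue
            out.append((pep, start + 1, end))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def label_columns_and_group(
    q_aln: str, s_aln: str, q_start: int, s_start: int, matrix, sv_min: int = 10
) -> list[tuple]:
    """Independent event extraction: label every column, then group.

    Returns tuples (type, tge_start, tge_end, ref_start, ref_end, tge_seq,
    ref_seq) in left-to-right order.
    """
    labels = []
    for qc, sc in zip(q_aln, s_aln):
        if qc == "-":
            labels.append("D")
        elif sc == "-":
            labels.append("I")
        elif qc == sc:
            labels.append("=")
        else:
            labels.append("S")
    events = []
    i = 0
    qpos = q_start - 1
    spos = s_start - 1
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        seg_q = q_aln[i:j]
        seg_s = s_aln[i:j]
        nq = sum(c != "-" for c in seg_q)
        ns = sum(c != "-" for c in seg_s)
        length = j - i
        if labels[i] == "S":
            if length >= sv_min:
                etype = "SV"
            elif length == 1:
                etype = "SSAP" if matrix[seg_q, seg_s] > 0 else "SAP"
            else:
                allpos = all(matrix[x, y] > 0 for x, y in zip(seg_q, seg_s))
                etype = "SALT" if allpos else "ALT"
            events.append((etype, qpos + 1, qpos + length, spos + 1, spos + length,
                           seg_q, seg_s))
        elif labels[i] == "D":
            etype = "SV" if length >= sv_min else "DEL"
            events.append((etype, qpos, qpos, spos + 1, spos + length, "", seg_s))
        elif labels[i] == "I":
            etype = "SV" if length >= sv_min else "INS"
            events.append((etype, qpos + 1, qpos + length, spos, spos, seg_q, ""))
        qpos += nq
        spos += ns
        i = j
    return events


def strip_mods_oracle(peptide: str) -> str:
    return re.sub(r"\[[^\]]*\]|\([^)]*\)", "", peptide).upper()
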