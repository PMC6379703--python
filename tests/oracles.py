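"""Independent brute-force oracles used to cross-check the implementation.

Nothing here imports the algorithms it checks: site scanning is a plain
character-by-character sliding window, panel search enumerates every enzyme
subset with its own labeled-fragment arithmetic, and the duplex oracle walks
anti-diagonals instead of the implementation's dynamic-programming recurrence.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def naive_match(seq: str, pat: str, p: int) -> bool:
    for i, code in enumerate(pat):
        c = seq[p + i]
        if c == "N" or c not in IUPAC[code]:
            return False
    return True


def naive_cuts(seq: str, circular: bool, enzymes) -> list[int]:
    """All top-strand cut coordinates, sorted, deduplicated.

    enzymes: iterable of objects with .recognition, .cut_top, .cut_bottom.
    """
    n = len(seq)
    cuts: set[int] = set()
    scan = seq + seq if circular else seq
    for e in enzymes:
        pat = e.recognition
        L = len(pat)
        for strand_pat, off in ((pat, e.cut_top), (rc(pat), L - e.cut_bottom)):
            for p in range(n if circular else n - L + 1):
                if p + L > len(scan):
                    continue
                if naive_match(scan, strand_pat, p):
                    c = p + off
                    if circular:
                        cuts.add(c % n)
                    elif 0 <= c <= n:
                        cuts.add(c)
        # palindromic sites: the bottom-strand recognition coincides with the
        # top one but its cut offset may differ
    return sorted(cuts)


def naive_fragments(seq: str, circular: bool, enzymes) -> list[int]:
    n = len(seq)
    cuts = naive_cuts(seq, circular, enzymes)
    if circular:
        if not cuts:
            return [n]
        return sorted(
            ((cuts[(i + 1) % len(cuts)] - cuts[i]) % n) or n
            for i in range(len(cuts))
        )
    bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def naive_labeled(seq: str, label_pos: int, enzymes) -> tuple[int, bool]:
    cuts = [c for c in naive_cuts(seq, False, enzymes) if label_pos < c < len(seq)]
    if not cuts:
        return len(seq) - label_pos, True
    return cuts[0] - label_pos, False


def exhaustive_panels(variant_seqs, label_positions, library, resolution, max_k):
    """All minimal-size enzyme subsets giving pairwise length gaps >= resolution.

    library: dict name -> enzyme object.  Returns (size, [frozenset, ...]).
    """
    import itertools

    names = sorted(library)
    for k in range(1, max_k + 1):
        winners = []
        for combo in itertools.combinations(names, k):
            enz = [library[c] for c in combo]
            lens = sorted(
                naive_labeled(s, lp, enz)[0]
                for s, lp in zip(variant_seqs, label_positions)
            )
            if all(b - a >= resolution for a, b in zip(lens, lens[1:])):
                winners.append(frozenset(combo))
        if winners:
            return k, winners
    return None, []


def pair_score(a: str, b: str, allow_gu: bool) -> float:
    if (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return 1.0
    if allow_gu and (a, b) in {("G", "T"), ("T", "G")}:
        return 0.5
    return 0.0


def diagonal_duplex_hits(dock: str, target: str, min_len: int, allow_gu: bool):
    """Maximal antiparallel complementary runs found by anti-diagonal walking.

    Returns a set of (dock_start, target_start, length, score) tuples.
    dock[i] pairs target[j]; extending the duplex pairs (i+1, j-1), so runs
    live on constant (i + j) anti-diagonals.
    """
    n, m = len(dock), len(target)
    hits = set()
    for d in range(n + m - 1):
        i_lo = max(0, d - m + 1)
        i_hi = min(n - 1, d)
        run_len, run_score, run_start = 0, 0.0, None
        for i in range(i_lo, i_hi + 1):
            j = d - i
            s = pair_score(dock[i], target[j], allow_gu)
            if s > 0:
                if run_len == 0:
                    run_start = i
                run_len += 1
                run_score += s
            else:
                if run_len >= min_len:
                    hits.add((run_start, d - (run_start + run_len - 1), run_len, run_score))
                run_len, run_score, run_start = 0, 0.0, None
        if run_len >= min_len:
            hits.add((run_start, d - (run_start + run_len - 1), run_len, run_score))
    return hits


def naive_pam_guides(seq: str, lo: int, hi: int):
    """(pam_pos, strand, spacer, cut) for every NGG PAM with full 20-nt spacer."""
    out = []
    n = len(seq)
    for p in range(n - 2):
        if seq[p + 1 : p + 3] == "GG" and lo <= p < hi and p - 20 >= 0:
            spacer = seq[p - 20 : p]
            if "N" not in spacer and p - 3 >= 0:
                out.append((p, +1, spacer, p - 3))
    for p in range(n - 2):
        if seq[p : p + 2] == "CC" and lo <= p < hi and p + 23 <= n:
            spacer = rc(seq[p + 3 : p + 23])
            if "N" not in spacer and p + 6 <= n:
                out.append((p, -1, spacer, p + 6))
    return sorted(out)


def naive_cuts_np(seq: str, circular: bool, enzymes):
    """Vectorized position-wise window matching (independent of the regex path).

    For each window offset the candidate base is tested against the IUPAC
    set; a position matches when every offset does.  Same semantics as
    naive_cuts, computed with numpy boolean algebra.
    """
    import numpy as np

    n = len(seq)
    scan = seq + seq if circular else seq
    arr = np.frombuffer(scan.encode(), dtype=np.uint8)
    cuts: set[int] = set()
    for e in enzymes:
        pat = e.recognition
        L = len(pat)
        for strand_pat, off in ((pat, e.cut_top), (rc(pat), L - e.cut_bottom)):
            limit = (n if circular else n - L + 1)
            if limit <= 0 or len(scan) < L:
                continue
            ok = np.ones(len(scan) - L + 1, dtype=bool)
            for i, code in enumerate(strand_pat):
                allowed = np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)
                ok &= np.isin(arr[i : i + len(ok)], allowed)
            for p in np.nonzero(ok)[0]:
                if p >= limit:
                    continue
                c = int(p) + off
                if circular:
                    cuts.add(c % n)
                elif 0 <= c <= n:
                    cuts.add(c)
    return sorted(cuts)


def fragments_from_cuts(n: int, circular: bool, cuts) -> list[int]:
    if circular:
        if not cuts:
            return [n]
        return sorted(
            ((cuts[(i + 1) % len(cuts)] - cuts[i]) % n) or n
            for i in range(len(cuts))
        )
    bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))
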