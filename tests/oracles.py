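"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately re-derive the same contracts by a different route:
the SSR oracle tests every (position, unit-length) pair quadratically;
the e-PCR oracle slides every pattern over every template position and
pairs footprints exhaustively. They share no code with the package
implementations they check.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# --- SSR mining oracle -------------------------------------------------------

def _primitive(motif: str) -> bool:
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]):
    """Every maximal left-anchored perfect tract, via per-position scan.

    Returns sorted tuples (start, end, motif, repeat_count, unit_length)
    with 1-based inclusive coordinates, after suppressing tracts contained
    in the span of a shorter-unit tract.
    """
    n = len(seq)
    hits = []
    for k in range(1, 7):
        thr = min_repeats[k]
        for p in range(0, n - k + 1):
            motif = seq[p : p + k]
            if "N" in motif or not _primitive(motif):
                continue
            # left anchor: p must start its period-k region
            if p >= 1 and p - 1 + k < n:
                prev = seq[p - 1]
                if prev != "N" and prev == seq[p - 1 + k]:
                    continue
            c = 1
            while seq[p + c * k : p + (c + 1) * k] == motif:
                c += 1
            if c >= thr:
                hits.append((p + 1, p + c * k, motif, c, k))
    kept = []
    for h in hits:
        contained = any(
            o[4] < h[4] and o[0] <= h[0] and h[1] <= o[1] for o in hits if o != h
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h[0], h[4]))
    return kept


def brute_force_merge(tracts, max_interrupt: int):
    """Chain-merge tracts (sorted by start) into (start, end, type) spans."""
    if not tracts:
        return []
    out = []
    chain = [tracts[0]]
    for t in tracts[1:]:
        if t[0] - chain[-1][1] - 1 <= max_interrupt:
            chain.append(t)
        else:
            out.append(_span(chain))
            chain = [t]
    out.append(_span(chain))
    return out


def _span(chain):
    if len(chain) == 1:
        s, e, motif, c, k = chain[0]
        return (s, e, f"p{k}")
    return (chain[0][0], chain[-1][1], "c")


# --- e-PCR oracle ------------------------------------------------------------

def naive_matches(pattern: str, seq: str, max_mm: int = 0, seed: int = 0,
                  seed_at_end: bool = True):
    """(0-based start, mismatches) by checking every window position."""
    m, n = len(pattern), len(seq)
    out = []
    for i in range(n - m + 1):
        mm = 0
        ok = True
        for j in range(m):
            a, b = pattern[j], seq[i + j]
            if a == b and a != "N":
                continue
            in_seed = (j >= m - seed) if seed_at_end else (j < seed)
            if in_seed:
                ok = False
                break
            mm += 1
            if mm > max_mm:
                ok = False
                break
        if ok:
            out.append((i, mm))
    return out


def naive_epcr(forward: str, reverse: str, seq: str, max_mm: int = 0,
               seed: int = 0, max_product: int = 5000,
               min_product: int | None = None):
    """All amplicons as (start, end, size, orientation, mm_f, mm_r),
    1-based inclusive, deduplicated by coordinates, sorted."""
    if min_product is None:
        min_product = len(forward) + len(reverse)
    f_plus = naive_matches(forward, seq, max_mm, seed, True)
    f_minus = naive_matches(revcomp(forward), seq, max_mm, seed, False)
    r_plus = naive_matches(reverse, seq, max_mm, seed, True)
    r_minus = naive_matches(revcomp(reverse), seq, max_mm, seed, False)
    lf, lr = len(forward), len(reverse)
    seen = set()
    hits = []

    def emit(start0, end0, orient, mf, mr):
        size = end0 - start0 + 1
        if not (min_product <= size <= max_product):
            return
        key = (start0 + 1, end0 + 1)
        if key in seen:
            return
        seen.add(key)
        hits.append((start0 + 1, end0 + 1, size, orient, mf, mr))

    for fi, fmm in f_plus:
        for ri, rmm in r_minus:
            if ri > fi + lf - 1:
                emit(fi, ri + lr - 1, "+", fmm, rmm)
    for ri, rmm in r_plus:
        for fi, fmm in f_minus:
            if fi > ri + lr - 1:
                emit(ri, fi + lf - 1, "-", fmm, rmm)
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
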