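"""Independent brute-force oracles used to check the implementation.

These deliberately use the most naive formulation of each rule and share
no code with the package internals they validate.
"""

from __future__ import annotations

from gvannot.genome_io import CircularGenome, reverse_complement
from gvannot.orf_annotation import STOP_CODONS


def brute_force_orfs(genome: CircularGenome, min_codons: int) -> set:
    """Every (position, strand) triple tested independently: walk each ATG
    to its first downstream stop; keep the longest ORF per stop."""
    L = genome.length
    res = set()
    for strand in ("sense", "antisense"):
        s = genome.seq if strand == "sense" else reverse_complement(genome.seq)
        walkable = s + s + s if genome.circular else s
        per_stop: dict[int, tuple[int, int]] = {}
        scan_limit = L if genome.circular else len(s) - 2
        for a in range(scan_limit):
            if walkable[a:a + 3] != "ATG":
                continue
            q = a + 3
            stop = None
            while q + 3 <= len(walkable):
                if walkable[q:q + 3] in STOP_CODONS:
                    stop = q
                    break
                q += 3
            if stop is None:
                continue
            if genome.circular and stop + 3 - a > L:
                continue  # would overlap itself around the circle
            n_aa = (stop - a) // 3
            key = stop % L if genome.circular else stop
            prev = per_stop.get(key)
            if prev is None or n_aa > prev[1]:
                per_stop[key] = (a % L if genome.circular else a, n_aa)
        for key, (a, n_aa) in per_stop.items():
            if n_aa < min_codons:
                continue
            first = a
            last = (key + 2) % L if genome.circular else key + 2
            if strand == "sense":
                gf, gl = first, last
            else:
                gf, gl = L - 1 - last, L - 1 - first
            res.add((gf + 1, gl + 1, strand, n_aa))
    return res


def sliding_early_pairs(window: str, gap_min: int = 20, gap_max: int = 40) -> set:
    """Position-by-position check of the TATA + CAGT/CATT pairing rule."""
    hits = set()
    n = len(window)
    for t in range(n - 3):
        if window[t:t + 4] != "TATA":
            continue
        for i in range(n - 3):
            if window[i:i + 4] not in ("CAGT", "CATT"):
                continue
            gap = i - (t + 4)
            if gap_min <= gap <= gap_max:
                hits.add((t + 1, i + 1, window[i:i + 4]))
    return hits


def sliding_late_hits(window: str) -> set:
    hits = set()
    for i in range(len(window) - 4):
        if window[i:i + 5] in ("ATAAG", "TTAAG", "GTAAG"):
            hits.add((i + 1, window[i:i + 5]))
    return hits


def hamming_core_hits(genome: CircularGenome, max_mismatch: int) -> set:
    """Exhaustive Hamming scan for TTAAT(G/A)TCGA on both strands."""
    consensi = ("TTAATGTCGA", "TTAATATCGA")
    L = genome.length
    ext = genome.seq + (genome.seq[:9] if genome.circular else "")
    hits = set()
    for i in range(len(ext) - 9):
        word = ext[i:i + 10]
        if "N" in word:
            continue
        d_f = min(sum(a != b for a, b in zip(word, c)) for c in consensi)
        rc = reverse_complement(word)
        d_r = min(sum(a != b for a, b in zip(rc, c)) for c in consensi)
        if d_f <= max_mismatch:
            hits.add((i + 1, "forward", d_f))
        if d_r <= max_mismatch:
            hits.add((i + 1, "reverse", d_r))
    return hits


def brute_force_runs(points: list[tuple[int, int]], min_len: int) -> list:
    """Maximal diagonal/antidiagonal runs by direct enumeration."""
    runs = []
    k = 0
    while k < len(points):
        best = [points[k]]
        for step in (1, -1):
            run = [points[k]]
            m = k
            while m + 1 < len(points) and \
                    points[m + 1][0] == points[m][0] + 1 and \
                    points[m + 1][1] == points[m][1] + step:
                run.append(points[m + 1])
                m += 1
            if len(run) > len(best):
                best = run
        direction = "collinear"
        if len(best) >= 2 and best[1][1] < best[0][1]:
            direction = "reverse"
        runs.append((tuple(best), direction))
        k += len(best)
    return [r for r in runs if len(r[0]) >= min_len]
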