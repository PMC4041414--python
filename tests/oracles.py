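"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library's vectorized/optimized code paths.
"""

from lhekit.sites import reverse_complement


def bruteforce_scan(genome, target, k_max):
    """Position-by-position k-mismatch scan over both strands."""
    L = target.length
    out = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            for strand, cand in (("+", window), ("-", reverse_complement(window))):
                d = sum(
                    1
                    for c, t in zip(cand, target.sequence)
                    if c != t or c not in "ACGT"
                )
                if d <= k_max:
                    out.append((chrom, start, strand, d))
    out.sort(key=lambda h: (h[0], h[1], h[2]))
    return out
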