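"""Deliberately naive re-implementations used as independent oracles.

These stay dict-and-loop based, sharing no code with the package, so that
agreement between the two routes is meaningful.
"""

_STOPS = {"TAA", "TAG", "TGA"}


def naive_elongator_count(seq: str) -> tuple[dict[str, int], int]:
    """Sliding-window recount of elongator codons: drop the first codon,
    drop a terminal stop, skip ambiguous triplets, tally the rest."""
    seq = seq.upper().replace("U", "T")
    n_full = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    body = codons[1:]
    if body and body[-1] in _STOPS:
        body = body[:-1]
    tally: dict[str, int] = {}
    total = 0
    for codon in body:
        if any(base not in "ACGT" for base in codon):
            continue
        tally[codon] = tally.get(codon, 0) + 1
        if codon not in _STOPS:
            total += 1
    return tally, total


def naive_weighted_usage(gene_counts, gene_freqs):
    """Double loop over genes x 64 codons: sum count * frequency."""
    usage = [0.0] * 64
    for gene, weight in gene_counts.items():
        freqs = gene_freqs[gene]
        for slot in range(64):
            usage[slot] += weight * freqs[slot]
    return usage
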