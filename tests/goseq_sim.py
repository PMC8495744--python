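"""Simulation helpers for the length-bias enrichment tests."""

from __future__ import annotations

import numpy as np

from ucescan.goenrich import GeneBias


def length_driven_table(rng, n_genes=300, n_uniform_terms=10,
                        term_size=50, enriched_term=None, enrichment=3.0,
                        capture_power=6.0):
    """Genes with lognormal lengths; hit probability purely length-driven;
    one term ("T_long") capturing long genes with no true hit effect.

    When ``enriched_term`` is set, membership in that (uniformly drawn)
    term multiplies the hit probability: a genuine enrichment signal on
    top of the length bias.
    """
    lengths = np.exp(rng.normal(7.0, 1.2, size=n_genes))
    p_hit = np.clip(lengths / np.quantile(lengths, 0.97), 0.02, 0.9)

    terms_by_gene: list[set[str]] = [set() for _ in range(n_genes)]
    w = lengths ** capture_power
    long_members = rng.choice(n_genes, size=term_size, replace=False,
                              p=w / w.sum())
    for g in long_members:
        terms_by_gene[g].add("T_long")
    for t in range(n_uniform_terms):
        for g in rng.choice(n_genes, size=term_size, replace=False):
            terms_by_gene[g].add(f"T{t:02d}")
    if enriched_term is not None:
        members = rng.choice(n_genes, size=term_size, replace=False)
        for g in members:
            terms_by_gene[g].add(enriched_term)
            p_hit[g] = min(0.95, p_hit[g] * enrichment)

    hits = rng.random(n_genes) < p_hit
    # guard against degenerate draws
    if hits.sum() < 2:
        hits[:2] = True
    if (~hits).sum() < 2:
        hits[-2:] = False
    return [
        GeneBias(gene_id=f"g{i:04d}", bias=float(lengths[i]),
                 is_hit=bool(hits[i]), terms=terms_by_gene[i])
        for i in range(n_genes)
    ]
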