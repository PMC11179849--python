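import numpy as np
import pytest

import diploscan as ds


@pytest.fixture(scope="session")
def small_sim():
    """A 300-kb synthetic diploid with the default variant rates."""
    params = ds.SimParams(genome_length=300_000, seed=1)
    reference = ds.generate_reference(params)
    pair, truth = ds.plant_variants(reference, params)
    return params, reference, pair, truth


@pytest.fixture(scope="session")
def small_called(small_sim):
    """Alignment blocks and called variants for the 300-kb fixture."""
    _params, reference, pair, _truth = small_sim
    blocks = []
    for chrom in sorted(pair.phase0):
        blocks.extend(
            ds.anchor_align(pair.phase0[chrom], pair.phase1[chrom],
                            ref_name=chrom, query_name=chrom)
        )
    te_mask = {}
    for t in reference.tes:
        te_mask.setdefault(t.chrom, []).append((t.start, t.end))
    variants = ds.extract_variants(blocks, pair.phase0, pair.phase1,
                                   te_mask=te_mask)
    return blocks, variants


@pytest.fixture(scope="session")
def ltr_sim():
    """A 2-Mb diploid whose TE loci are all LTR retrotransposons, half of
    them realised as phase-1 insertions carrying a 5-nt TSD."""
    lib = [c for c in ds.default_te_library() if c.order == "LTR"]
    params = ds.SimParams(genome_length=2_000_000, seed=11, te_library=lib,
                          het_te_fraction=1.0)
    reference = ds.generate_reference(params)
    pair, truth = ds.plant_variants(reference, params)
    blocks = ds.anchor_align(pair.phase0["chr1"], pair.phase1["chr1"],
                             ref_name="chr1", query_name="chr1")
    te_mask = {"chr1": [(t.start, t.end) for t in reference.tes]}
    variants = ds.extract_variants(blocks, pair.phase0, pair.phase1,
                                   te_mask=te_mask)
    return params, reference, pair, truth, blocks, variants


@pytest.fixture(scope="session")
def make_counts():
    """Factory for plain binomial-split count tables (ASE statistical tests)."""
    import pandas as pd

    def _make(rng, n_genes, depth, ratios, n_reps=3, organ="o1"):
        rows = []
        for g in range(n_genes):
            r = ratios[g] if hasattr(ratios, "__len__") else ratios
            for rep in range(n_reps):
                n = int(rng.poisson(depth))
                x = int(rng.binomial(n, r)) if n else 0
                rows.append({"gene": f"g{g:04d}", "organ": organ,
                             "replicate": rep, "count_p0": x,
                             "count_p1": n - x})
        return pd.DataFrame(rows)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(123)
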