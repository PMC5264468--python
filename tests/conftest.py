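import dataclasses

import pandas as pd
import pytest

from xci_allelic import pipeline, simulate


def make_pileup(rows):
    """Build a pileup DataFrame from (chrom, pos, ref, counts-dict[, quals-dict]).

    When quals are omitted, each base with count c gets qualsum 30*c
    (i.e. uniform phred-30 reads).
    """
    out = []
    for row in rows:
        chrom, pos, ref, counts = row[:4]
        quals = row[4] if len(row) > 4 else {b: 30.0 * c for b, c in counts.items()}
        rec = {"chrom": chrom, "pos": pos, "ref": ref}
        for b in "ACGT":
            rec[b] = counts.get(b, 0)
            rec["q" + b] = quals.get(b, 0.0) if counts.get(b, 0) else 0.0
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def tiny_bundle():
    return simulate.simulate_dataset(simulate.TINY)


@pytest.fixture(scope="session")
def standard_bundle():
    return simulate.simulate_dataset(simulate.STANDARD)


@pytest.fixture(scope="session")
def standard_run(standard_bundle):
    b = standard_bundle
    return pipeline.run_pipeline(b["manifest"], b["pileups"], b["genes"],
                                 pipeline.PipelineParams())


@pytest.fixture(scope="session")
def discovery_bundle():
    """Standard-scale dataset with a large non-variant block for
    false-positive monitoring."""
    cfg = dataclasses.replace(simulate.STANDARD, n_nonvariant_positions=10_000)
    return simulate.simulate_dataset(cfg)
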