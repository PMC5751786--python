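import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncons.genomic_io import AnnotationSet, ExpressionMatrix, TranscriptModel

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tx(tid, chrom="chr1", strand="+", exons=((100, 300),), biotype="unknown",
       gene=None):
    """Shorthand transcript builder."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid,
        chrom=chrom,
        strand=strand,
        exons=[tuple(e) for e in exons],
        biotype=biotype,
    )


@pytest.fixture
def expr_of():
    """Build an ExpressionMatrix from a dict feature -> list of TPMs."""

    def build(data, sample_meta=None, prefix="s"):
        n = len(next(iter(data.values()))) if data else 0
        cols = [f"{prefix}{i}" for i in range(n)]
        df = pd.DataFrame(
            {c: [data[f][i] for f in data] for i, c in enumerate(cols)},
            index=list(data),
        )
        return ExpressionMatrix(df.astype(float), sample_meta or {})

    return build


@pytest.fixture
def annotation_of():
    def build(*transcripts):
        return AnnotationSet(transcripts)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
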