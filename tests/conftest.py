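import numpy as np
import pandas as pd
import pytest

import sialotools as st


@pytest.fixture(scope="session")
def sim_cfg():
    return st.SimulationConfig(seed=11, n_host_transcripts=200)


@pytest.fixture(scope="session")
def sim_world(sim_cfg):
    """One simulated study shared across tests: transcripts, viral CDS,
    truth table, hits and counts."""
    transcripts, viral, truth = st.simulate_transcriptome(sim_cfg)
    hits = st.simulate_hits(truth, sim_cfg)
    counts, samples = st.simulate_counts(truth, sim_cfg)
    return {
        "cfg": sim_cfg, "transcripts": transcripts, "viral": viral,
        "truth": truth, "hits": hits, "counts": counts, "samples": samples,
    }


@pytest.fixture(scope="session")
def lexicon():
    return st.default_lexicon()


def make_hit(query_id="t1", subject_id="s1", desc="some protein", db="NR",
             pident=80.0, qstart=1, qend=300, sstart=1, send=100,
             bitscore=100.0, qlen=500, slen=120, evalue=1e-30):
    return st.HitTableRow(
        query_id=query_id, subject_id=subject_id, subject_desc=desc,
        db_tag=db, pident=pident, align_len=send - sstart + 1,
        qstart=qstart, qend=qend, sstart=sstart, send=send,
        evalue=evalue, bitscore=bitscore, qlen=qlen, slen=slen,
    )


@pytest.fixture
def hit_factory():
    return make_hit
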