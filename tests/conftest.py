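import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from satarray import arrays, htself, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def transcript_pool():
    """30 transcripts with truth table and noise-free orientation evidence."""
    spec = simulate.SimTranscriptomeSpec(n_transcripts=30, seed=7)
    transcripts, truth = simulate.gen_transcriptome(spec)
    hits, ests = simulate.gen_hits_and_ests(truth, error_rate=0.0, seed=8)
    return transcripts, truth, hits, ests


@pytest.fixture(scope="session")
def small_design(transcript_pool):
    """Probe design for the first 8 pool transcripts, screened against them."""
    from satarray import probes
    transcripts, truth, hits, ests = transcript_pool
    recs = transcripts[:8]
    db = {t.id: t.sequence for t in recs}
    design = probes.design_array(list(recs), hits, ests, db)
    return recs, db, hits, ests, design


@pytest.fixture(scope="session")
def simulated_experiment():
    """One-timepoint experiment: 200 paired transcripts, planted folds."""
    design = simulate.gen_design(200, seed=21)
    plan = simulate.make_sat_de_plan(design, fraction_de=0.08,
                                     fold_magnitude=2.5, sat_correlation=0.9,
                                     seed=22)
    spec = simulate.SimArraySpec(design=design, n_timepoints=1,
                                 de_plan=plan, seed=23)
    features, truth, config = simulate.gen_array_signals(spec)
    flagged = arrays.compute_spot_flags(features)
    normalized = arrays.normalize(flagged, config)
    return {
        "design": design, "plan": plan, "spec": spec, "features": features,
        "truth": truth, "config": config, "flagged": flagged,
        "normalized": normalized,
    }
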