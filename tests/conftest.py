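import numpy as np
import pytest

from msaptools import peaks, sim


@pytest.fixture
def noise_free_config():
    """Small cohort with no CE noise: render is exact."""
    return sim.SimConfig(
        n_individuals=4,
        n_loci=60,
        state_probs=(0.55, 0.15, 0.20, 0.10),
        jitter_sd=0.0,
        dropout_p=0.0,
        spurious_rate=0.0,
        seed=42,
    )


@pytest.fixture
def noise_free_cohort(noise_free_config):
    truth = sim.simulate_states(noise_free_config)
    records = sim.render_peaks(truth)
    return truth, records


@pytest.fixture
def peak_csv(tmp_path, noise_free_cohort):
    _, records = noise_free_cohort
    path = tmp_path / "peaks.csv"
    peaks.write_peak_table(records, path)
    return path


def match_bins_to_loci(matrix, truth):
    """Map each bin to the truth locus with the same (noise-free) size."""
    size_to_locus = {float(s): j for j, s in enumerate(truth.locus_sizes)}
    mapping = {}
    for k, b in enumerate(matrix.loci):
        assert b.nominal_size_bp in size_to_locus, "bin does not match any true locus"
        mapping[k] = size_to_locus[b.nominal_size_bp]
    return mapping
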