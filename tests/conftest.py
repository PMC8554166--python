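import pandas as pd
import pytest

from extractprofiler.io import ProteinRecord
from extractprofiler.simulate import SimulationConfig, generate_proteome, simulate_observations


def make_obs(rows):
    """Build an observation table from (peptide, group, sample, rep, method,
    intensity, score) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_sequence", "group_id", "sample_id", "replicate_id",
            "method", "intensity", "psm_score",
        ],
    )


@pytest.fixture
def toy_db():
    return [
        ProteinRecord("pA", "AAAKCCCRDDDK"),          # 12 residues
        ProteinRecord("pB", "WWWWKGGGGRHHHH"),        # 14 residues
        ProteinRecord("pC", "MMMMMMMMK"),             # 9 residues
    ]


@pytest.fixture
def clean_sim():
    """Noise-free, penalty-free, complete-coverage single-extract simulation."""
    cfg = SimulationConfig(
        seed=11, n_proteins=12, noise_cv=0.0, dropout=0.0,
        detectability_penalty=1.0, complete_coverage=True,
        methods=("tryptic",), contaminant_fraction=0.0,
        generate_decoys=False, n_spurious_groups=0,
        extract_profiles={"V": 1.0},
    )
    proteome, truth = generate_proteome(cfg)
    observations, groups = simulate_observations(proteome, truth, cfg)
    return cfg, proteome, truth, observations, groups
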