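import numpy as np
import pandas as pd
import pytest

from psiforge import io, psi_quant, synthetic


@pytest.fixture()
def hotspot_config():
    """Small single-molecule Ψ-seq config with the three-site 18S hotspot."""
    return synthetic.SimPsiConfig(
        molecule_lengths={"18S-like": 500},
        sites=[
            synthetic.PsiSite("18S-like", 105, 0.5, "SNORA_001"),
            synthetic.PsiSite("18S-like", 109, 0.25, "SNORA_002"),
            synthetic.PsiSite("18S-like", 119, 0.8, "SNORA_003"),
        ],
        termination_efficiency=1.0,
        background_stop_rate=0.01,
        coverage=300,
        seed=11,
    )


@pytest.fixture()
def sam_of_reads(tmp_path):
    """Write explicit (molecule, start, end, name) reads to a SAM file."""

    def _write(reads, reference_lengths, name="reads.sam"):
        path = tmp_path / name
        io.write_sam(path, reference_lengths, io.sort_reads(list(reads)))
        return path

    return _write


def matrix_from_values(values: pd.DataFrame, min_coverage: int = 1) -> psi_quant.PsiRatioMatrix:
    """Wrap a plain sites × samples DataFrame as a PsiRatioMatrix."""
    ids = values.index.to_series().astype(str)
    split = ids.str.split(":", expand=True)
    sites = pd.DataFrame(
        {
            "site_id": values.index,
            "molecule": split[0].values,
            "position": split[1].astype(int).values if split.shape[1] > 1 else 1,
            "guides": "",
        }
    )
    coverage = values.notna().astype(int) * 1000
    return psi_quant.PsiRatioMatrix(values=values, coverage=coverage, sites=sites,
                                    min_coverage=min_coverage)


@pytest.fixture()
def ratio_matrix_factory():
    return matrix_from_values


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
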