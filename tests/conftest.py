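import numpy as np
import pandas as pd
import pytest

from tetrapop.core import FrequencyPanel, GenotypeMatrix


def make_frequency_panel(freqs, populations, n_chr=0, outgroup_freq=None,
                         polarizable=True, positions=None, scaffold="scaffold_1"):
    """FrequencyPanel straight from a sites x populations frequency array."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n_sites = freqs.shape[0]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "position": positions,
            "ref": "A",
            "alt": "T",
            "derived_is_alt": True,
            "polarizable": polarizable,
        }
    )
    n_chr_arr = np.full(freqs.shape, n_chr, dtype=int)
    prov = np.full(freqs.shape, "G", dtype="U1")
    if outgroup_freq is None:
        outgroup_freq = np.zeros(n_sites)
    return FrequencyPanel(
        sites=sites,
        populations=list(populations),
        freq=freqs,
        n_chr=n_chr_arr,
        provenance=prov,
        outgroup_freq=np.asarray(outgroup_freq, dtype=float),
    )


def make_genotype_matrix(dosage, populations, ploidy=None, positions=None):
    """GenotypeMatrix from a sites x samples dosage array and a pop map
    given as {label: n_samples} consumed in column order."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_sites, n_samples = dosage.shape
    samples, pop_map, ploidies = [], {}, []
    i = 0
    for label, spec in populations.items():
        n, k = spec if isinstance(spec, tuple) else (spec, 4)
        names = [f"{label}_{j + 1}" for j in range(n)]
        samples += names
        pop_map[label] = names
        ploidies += [k] * n
        i += n
    assert i == n_samples
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"scaffold": "scaffold_1", "position": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(
        sites=sites,
        dosage=dosage,
        samples=samples,
        ploidy=np.array(ploidy if ploidy is not None else ploidies, dtype=np.int16),
        populations=pop_map,
    )


@pytest.fixture
def tiny_gff(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "scaffold_6\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
        "scaffold_6\ttest\tmRNA\t100\t500\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
        "scaffold_6\ttest\tgene\t900\t1400\t.\t-\t.\tID=geneB\n"
        "scaffold_7\ttest\tgene\t10\t60\t.\t.\t.\tID=geneC\n"
    )
    return path
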