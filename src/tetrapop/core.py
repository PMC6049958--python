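"""Core in-memory containers shared across the pipeline.

The package works on biallelic SNP panels from autotetraploid populations
(allele dosages 0..4 per individual) with an outgroup panel of possibly
different ploidy used only for polarization. Two containers carry almost
all data flow:

* :class:`GenotypeMatrix` — sites x samples integer dosages of the ALT
  allele, with per-site metadata and a sample -> population map.
* :class:`FrequencyPanel` — per-site, per-population derived-allele
  frequencies polarized against the outgroup consensus, with chromosome
  counts and a provenance flag (genotype-based, read-count fallback, or
  missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: provenance codes for FrequencyPanel entries
PROV_GENOTYPE = "G"
PROV_READCOUNT = "R"
PROV_MISSING = "M"


@dataclass
class GeneAnnotation:
    """A gene interval in 1-based closed coordinates (as in GFF3)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a set of samples.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``scaffold, position, ref, alt``; one row per SNP, sorted
        by (scaffold, position). Positions are 1-based (VCF convention).
    dosage : numpy.ndarray
        ``(n_sites, n_samples)`` int16 count of the ALT allele per sample;
        ``MISSING`` (-1) marks a filtered or uncalled genotype.
    samples : list of str
    ploidy : numpy.ndarray
        Per-sample ploidy (4 for tetraploid focal samples; the outgroup
        panel may be diploid or haploid).
    populations : dict
        population label -> list of sample names.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    samples: list
    ploidy: np.ndarray
    populations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        self.ploidy = np.asarray(self.ploidy, dtype=np.int16)
        if (self.ploidy <= 0).any():
            raise ValueError("ploidy must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str) -> np.ndarray:
        """Column indices of the samples belonging to *population*."""
        if population not in self.populations:
            raise KeyError(f"population {population!r} not in sample map")
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in self.populations[population]])


@dataclass
class FrequencyPanel:
    """Derived-allele frequencies per site and population.

    ``freq[i, k]`` is the frequency of the derived allele (the allele not
    carried by the outgroup consensus) at site *i* in population *k*;
    NaN marks a missing entry. ``n_chr[i, k]`` is the number of chromosomes
    the estimate is based on (4 x genotyped tetraploid individuals for
    genotype-based entries, 0 where missing). ``provenance`` holds one of
    the ``PROV_*`` codes per entry.

    ``sites`` carries ``scaffold, position, ref, alt, derived_is_alt,
    polarizable``; unpolarizable sites (outgroup missing or polymorphic
    beyond the configured threshold) keep their rows but are excluded from
    polarization-dependent statistics.
    """

    sites: pd.DataFrame
    populations: list
    freq: np.ndarray
    n_chr: np.ndarray
    provenance: np.ndarray
    outgroup_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_sites, n_pops = len(self.sites), len(self.populations)
        if self.freq.shape != (n_sites, n_pops):
            raise ValueError("freq shape does not match sites x populations")
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(self.freq, nan=0.5)
            if ((bad < 0) | (bad > 1)).any():
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in panel") from None

    def pop_freq(self, population: str) -> np.ndarray:
        return self.freq[:, self.pop_index(population)]

    def pop_n_chr(self, population: str) -> np.ndarray:
        return self.n_chr[:, self.pop_index(population)]

    @property
    def polarizable(self) -> np.ndarray:
        return self.sites["polarizable"].to_numpy(dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (site, population, p, n_chr, provenance)."""
        rows = []
        for k, pop in enumerate(self.populations):
            df = self.sites[["scaffold", "position"]].copy()
            df["population"] = pop
            df["p"] = self.freq[:, k]
            df["n_chr"] = self.n_chr[:, k]
            df["provenance"] = self.provenance[:, k]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class Window:
    """A block of consecutive usable SNPs on one scaffold.

    ``rows`` holds the row indices (into the site table the window was
    built from) of the usable SNPs it covers; ``start_bp``/``end_bp`` are
    the 1-based positions of the first and last SNP (closed span).
    """

    scaffold: str
    rows: np.ndarray
    start_bp: int
    end_bp: int
    full: bool

    @property
    def n_snps(self) -> int:
        return len(self.rows)
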