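"""Core genotype container shared by every analysis stage.

Genotypes are stored as alt-allele dosage codes (0, 1, 2) in a dense
``samples x loci`` int8 array, with :data:`MISSING` (-1) marking no-calls.
Locus metadata (chromosome, 1-based position, ref/alt alleles) lives in a
pandas DataFrame aligned column-for-column with the call matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel code for a missing genotype call.
MISSING: int = -1

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a set of samples at biallelic SNP loci.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``calls``).
    populations
        Mapping of sample id -> population label. Every sample must have a
        label; the labels partition the samples.
    loci
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions),
        one row per locus, aligned with the columns of ``calls``. Must be
        sorted by (chrom, pos) with unique positions per chromosome.
    calls
        int8 array of shape (n_samples, n_loci); entries in {0, 1, 2} count
        alt-allele copies, -1 is missing.
    depth
        Optional int32 array of per-genotype read depths, same shape as
        ``calls``.
    """

    samples: list[str]
    populations: dict[str, str]
    loci: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        if list(self.loci.columns[:4]) != list(LOCUS_COLUMNS):
            missing = set(LOCUS_COLUMNS) - set(self.loci.columns)
            if missing:
                raise ValueError(f"loci table missing columns: {sorted(missing)}")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if self.depth is not None and self.depth.shape != self.calls.shape:
            raise ValueError("depth layer shape differs from calls")
        unlabeled = [s for s in self.samples if s not in self.populations]
        if unlabeled:
            raise ValueError(f"samples without population label: {unlabeled}")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls contain codes outside {-1, 0, 1, 2}")
        # loci sorted by (chrom, pos), positions unique per chromosome
        key = self.loci[["chrom", "pos"]]
        if len(key) > 1:
            ordered = key.sort_values(["chrom", "pos"], kind="stable")
            if not (ordered.index == np.arange(len(key))).all():
                raise ValueError("loci must be sorted by (chrom, pos)")
            dup = key.duplicated().any()
            if dup:
                raise ValueError("duplicate (chrom, pos) locus coordinates")

    # -- basic properties --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        idx = [i for i, s in enumerate(self.samples) if self.populations[s] == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx, dtype=np.intp)

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    # -- subsetting (always copy; filters are functional) ------------------

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping loci at *index* (order preserved as given)."""
        index = np.asarray(index)
        return replace(
            self,
            loci=self.loci.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
            depth=None if self.depth is None else self.depth[:, index].copy(),
        )

    def take_samples(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.asarray([pos[s] for s in keep], dtype=np.intp)
        return replace(
            self,
            samples=list(keep),
            populations={s: self.populations[s] for s in keep},
            calls=self.calls[idx].copy(),
            depth=None if self.depth is None else self.depth[idx].copy(),
        )

    # -- per-population summaries used throughout --------------------------

    def genotype_counts(self, population: str) -> np.ndarray:
        """Per-locus genotype counts for one population.

        Returns an int64 array of shape (n_loci, 3) with columns
        (n_homref, n_het, n_homalt) over non-missing calls.
        """
        sub = self.calls[self.sample_indices(population)]
        out = np.empty((self.n_loci, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (sub == g).sum(axis=0)
        return out

    def alt_frequency(self, population: str) -> np.ndarray:
        """Per-locus alt-allele frequency in a population (NaN if no calls)."""
        counts = self.genotype_counts(population)
        n = counts.sum(axis=1)
        copies = counts[:, 1] + 2 * counts[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, copies / (2.0 * n), np.nan)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Exact equality of samples, loci, calls and (if present) depth."""
        if self.samples != other.samples or self.populations != other.populations:
            return False
        if not self.loci[list(LOCUS_COLUMNS)].equals(other.loci[list(LOCUS_COLUMNS)]):
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        if self.depth is not None and not np.array_equal(self.depth, other.depth):
            return False
        return True


@dataclass
class FilterReport:
    """Audit record emitted by a filtering step."""

    step: str
    n_samples_in: int
    n_samples_out: int
    n_loci_in: int
    n_loci_out: int
    details: pd.DataFrame = field(default_factory=pd.DataFrame)

    def as_row(self) -> dict:
        return {
            "step": self.step,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_loci_in": self.n_loci_in,
            "n_loci_out": self.n_loci_out,
        }
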