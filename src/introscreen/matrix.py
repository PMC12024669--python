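"""Core containers: diagnostic panels and sample-by-locus genotype matrices.

Genotype calls are stored as a dense ``int8`` array of foreign-allele
dosages: 0 (homozygous native), 1 (heterozygous), 2 (homozygous foreign),
and -1 for a missing call.  Polarity (which allele is "native") is fixed by
the :class:`DiagnosticPanel` and never reinterpreted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Genotype state codes (foreign-allele dosage).
HOM_NATIVE: int = 0
HET: int = 1
HOM_FOREIGN: int = 2
MISSING: int = -1

STATE_NAMES = {HOM_NATIVE: "HOM_NATIVE", HET: "HET", HOM_FOREIGN: "HOM_FOREIGN", MISSING: "MISSING"}

#: Single-character tokens used by the genotype TSV dialect.
TOKEN_TO_STATE = {"N": HOM_NATIVE, "H": HET, "F": HOM_FOREIGN, ".": MISSING}
STATE_TO_TOKEN = {v: k for k, v in TOKEN_TO_STATE.items()}


@dataclass(frozen=True)
class DiagnosticLocus:
    """One species-diagnostic biallelic SNP.

    Parameters
    ----------
    locus_id
        Unique identifier of the locus within a panel.
    native_allele, foreign_allele
        Single-base symbols for the allele fixed (or nearly fixed) in the
        native species and in the foreign species respectively.
    read_position
        1-based position of the variant within the amplicon read, when known.
    primer_fwd, primer_rev
        Optional primer sequences used to amplify the locus.
    """

    locus_id: str
    native_allele: str
    foreign_allele: str
    read_position: int | None = None
    primer_fwd: str | None = None
    primer_rev: str | None = None

    def __post_init__(self) -> None:
        if self.native_allele == self.foreign_allele:
            raise ValueError(
                f"locus {self.locus_id!r}: native and foreign alleles are identical "
                f"({self.native_allele!r})"
            )
        if self.read_position is not None and self.read_position < 1:
            raise ValueError(f"locus {self.locus_id!r}: read_position must be >= 1")


@dataclass(frozen=True)
class DiagnosticPanel:
    """An ordered collection of diagnostic loci."""

    loci: tuple[DiagnosticLocus, ...]

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("a panel needs at least one locus")
        seen: set[str] = set()
        for loc in self.loci:
            if loc.locus_id in seen:
                raise ValueError(f"duplicate locus id in panel: {loc.locus_id!r}")
            seen.add(loc.locus_id)

    @property
    def L(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def subset(self, locus_ids: Sequence[str]) -> "DiagnosticPanel":
        keep = set(locus_ids)
        return DiagnosticPanel(tuple(l for l in self.loci if l.locus_id in keep))


@dataclass
class GenotypeMatrix:
    """Samples x loci categorical genotype calls with a population map.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows).
    loci : list of str
        Ordered, unique locus identifiers (columns).
    calls : ndarray of int8, shape (n_samples, n_loci)
        Foreign-allele dosage codes; -1 marks a missing call.
    pops : dict
        Maps every sample id to a non-empty population label.
    depths : ndarray or None
        Optional per-call total read depth, same shape as ``calls``.
    panel : DiagnosticPanel or None
        When present, fixes allele polarity and must match ``loci``.
    parent_locus : list of str or None
        Optional parent-locus (e.g. RAD-tag) id per column, used by the
        one-SNP-per-locus filter.
    """

    samples: list[str]
    loci: list[str]
    calls: np.ndarray
    pops: dict[str, str]
    depths: np.ndarray | None = None
    panel: DiagnosticPanel | None = None
    parent_locus: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = self.calls.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} genotype rows")
        if len(self.loci) != L:
            raise ValueError(f"{len(self.loci)} locus ids for {L} genotype columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.loci)) != L:
            raise ValueError("locus ids are not unique")
        missing_pop = [s for s in self.samples if not self.pops.get(s)]
        if missing_pop:
            raise ValueError(
                "samples without a population label: " + ", ".join(missing_pop)
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depth table shape does not match genotype table")
        if self.panel is not None and self.panel.locus_ids != list(self.loci):
            raise ValueError("panel loci do not match matrix loci")
        if self.parent_locus is not None and len(self.parent_locus) != L:
            raise ValueError("parent_locus length does not match locus count")
        bad = ~np.isin(self.calls, (HOM_NATIVE, HET, HOM_FOREIGN, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        out: list[str] = []
        for s in self.samples:
            p = self.pops[s]
            if p not in out:
                out.append(p)
        return out

    def pop_labels(self) -> np.ndarray:
        """Per-row population labels as an object array."""
        return np.array([self.pops[s] for s in self.samples], dtype=object)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    # -- subsetting -----------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        samples = [self.samples[i] for i in idx]
        return GenotypeMatrix(
            samples=samples,
            loci=list(self.loci),
            calls=self.calls[idx, :],
            pops={s: self.pops[s] for s in samples},
            depths=None if self.depths is None else self.depths[idx, :],
            panel=self.panel,
            parent_locus=self.parent_locus,
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        loci = [self.loci[i] for i in idx]
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=loci,
            calls=self.calls[:, idx],
            pops=dict(self.pops),
            depths=None if self.depths is None else self.depths[:, idx],
            panel=None if self.panel is None else self.panel.subset(loci),
            parent_locus=None
            if self.parent_locus is None
            else [self.parent_locus[i] for i in idx],
        )

    def subset_population(self, population: str) -> "GenotypeMatrix":
        idx = [i for i, s in enumerate(self.samples) if self.pops[s] == population]
        if not idx:
            raise ValueError(f"no samples in population {population!r}")
        return self.take_samples(idx)

    # -- convenience ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Genotype calls as a DataFrame of single-character tokens."""
        tok = np.vectorize(STATE_TO_TOKEN.get)(self.calls)
        return pd.DataFrame(tok, index=self.samples, columns=self.loci)

    def missing_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).sum(axis=1)


@dataclass
class AlleleCounts:
    """Per-sample, per-locus read counts supporting each panel allele.

    ``n_native[i, l]`` and ``n_foreign[i, l]`` are the numbers of reads for
    sample ``i`` at locus ``l`` that carry the native and the foreign allele;
    their sum is the informative depth of the call.
    """

    samples: list[str]
    loci: list[str]
    n_native: np.ndarray
    n_foreign: np.ndarray

    def __post_init__(self) -> None:
        self.n_native = np.asarray(self.n_native, dtype=np.int64)
        self.n_foreign = np.asarray(self.n_foreign, dtype=np.int64)
        if self.n_native.shape != self.n_foreign.shape:
            raise ValueError("count tables must share a shape")
        if self.n_native.shape != (len(self.samples), len(self.loci)):
            raise ValueError("count table shape does not match sample/locus ids")
        if (self.n_native < 0).any() or (self.n_foreign < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.n_native + self.n_foreign


def merge_populations(
    matrix: GenotypeMatrix, groups: Mapping[str, Iterable[str]]
) -> GenotypeMatrix:
    """Relabel populations by merging groups of existing labels.

    ``groups`` maps each new label to the set of old labels it absorbs.
    Labels not mentioned in any group are kept as they are.  Every old
    label referenced must exist in the matrix.
    """
    existing = set(matrix.pops.values())
    relabel: dict[str, str] = {}
    for new, olds in groups.items():
        for old in olds:
            if old not in existing:
                raise ValueError(f"population {old!r} not present in matrix")
            relabel[old] = new
    new_pops = {s: relabel.get(p, p) for s, p in matrix.pops.items()}
    out = replace(matrix, pops=new_pops)
    return out
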