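"""Readers and writers for panels, genotype tables, popmaps and genepop.

The genotype TSV dialect is deliberately minimal: a header row
``sample<TAB>locus1<TAB>...`` followed by one row per sample whose cells are
the tokens ``N`` (homozygous native), ``H`` (heterozygous), ``F``
(homozygous foreign) and ``.`` (missing).  An optional depth table uses the
same layout with integer cells.  VCF input is read through cyvcf2 and
oriented against the diagnostic panel: a site whose REF matches the panel's
native allele is taken as-is, a site whose REF matches the foreign allele is
flipped, and a site matching neither allele is dropped with a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import (
    HET,
    HOM_FOREIGN,
    HOM_NATIVE,
    MISSING,
    STATE_TO_TOKEN,
    TOKEN_TO_STATE,
    DiagnosticLocus,
    DiagnosticPanel,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)

_PANEL_REQUIRED = ("locus_id", "native_allele", "foreign_allele")


def load_panel(path: str | Path) -> DiagnosticPanel:
    """Read a diagnostic panel from a tab-separated table.

    Required columns: ``locus_id``, ``native_allele``, ``foreign_allele``.
    Optional columns ``read_position``, ``primer_fwd``, ``primer_rev`` are
    preserved.  Loci keep file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _PANEL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"panel file {path}: missing column {col!r}")
    dups = df["locus_id"][df["locus_id"].duplicated()].tolist()
    if dups:
        raise ValueError(f"panel file {path}: duplicate locus id(s) {sorted(set(dups))}")
    loci = []
    for _, row in df.iterrows():
        pos = row.get("read_position")
        loci.append(
            DiagnosticLocus(
                locus_id=str(row["locus_id"]),
                native_allele=str(row["native_allele"]).upper(),
                foreign_allele=str(row["foreign_allele"]).upper(),
                read_position=None if pd.isna(pos) else int(float(pos)),
                primer_fwd=_opt(row.get("primer_fwd")),
                primer_rev=_opt(row.get("primer_rev")),
            )
        )
    return DiagnosticPanel(tuple(loci))


def _opt(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else str(v)


def write_panel(panel: DiagnosticPanel, path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "native_allele": l.native_allele,
            "foreign_allele": l.foreign_allele,
            "read_position": l.read_position,
            "primer_fwd": l.primer_fwd,
            "primer_rev": l.primer_rev,
        }
        for l in panel.loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>population`` table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"popmap {path}: duplicate sample id(s) {sorted(set(dups))}")
    return dict(zip(df["sample"], df["population"]))


def write_popmap(pops: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in pops.items():
            fh.write(f"{s}\t{p}\n")


def load_genotypes(
    path: str | Path,
    popmap: str | Path | Mapping[str, str],
    *,
    format: str = "tsv",
    panel: DiagnosticPanel | None = None,
    depths: str | Path | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix from a TSV table or a VCF.

    Every sample in the genotype file must appear in the popmap; samples
    present only in the popmap are ignored.
    """
    pops = load_popmap(popmap) if isinstance(popmap, (str, Path)) else dict(popmap)
    if format == "tsv":
        mat = _load_tsv(path, pops, panel, depths)
    elif format == "vcf":
        mat = _load_vcf(path, pops, panel)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return mat


def _check_popmap(samples: list[str], pops: Mapping[str, str]) -> dict[str, str]:
    absent = [s for s in samples if s not in pops]
    if absent:
        raise ValueError("samples missing from popmap: " + ", ".join(absent))
    return {s: pops[s] for s in samples}


def _load_tsv(path, pops, panel, depths) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column of a genotype TSV must be 'sample'")
    df = df.set_index("sample")
    samples = [str(s) for s in df.index]
    loci = [str(c) for c in df.columns]
    calls = np.empty((len(samples), len(loci)), dtype=np.int8)
    for j, col in enumerate(df.columns):
        tokens = df[col].astype(str).str.strip()
        unknown = sorted(set(tokens) - set(TOKEN_TO_STATE))
        if unknown:
            raise ValueError(f"{path}: unknown genotype token(s) {unknown} at locus {col!r}")
        calls[:, j] = [TOKEN_TO_STATE[t] for t in tokens]
    depth_arr = None
    if depths is not None:
        ddf = pd.read_csv(depths, sep="\t").set_index("sample")
        ddf = ddf.loc[samples, loci]
        depth_arr = ddf.to_numpy(dtype=np.int64)
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        calls=calls,
        pops=_check_popmap(samples, pops),
        depths=depth_arr,
        panel=panel,
    )


def _load_vcf(path, pops, panel) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is normally present
        raise ImportError("reading VCF requires the cyvcf2 package") from exc

    native_of = {} if panel is None else {l.locus_id: l for l in panel.loci}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    cols: list[np.ndarray] = []
    dropped: list[str] = []
    for var in vcf:
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        alt = var.ALT[0] if var.ALT else None
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: non-diploid genotype for sample {samples[i]!r} at {locus_id}"
                )
            if alleles[0] < 0 or alleles[1] < 0:  # half calls -> missing
                continue
            col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        flip = False
        if panel is not None:
            loc = native_of.get(locus_id)
            if loc is None:
                dropped.append(locus_id)
                continue
            if var.REF == loc.native_allele:
                flip = False
            elif var.REF == loc.foreign_allele:
                flip = True
            else:
                warnings.warn(
                    f"site {locus_id}: REF {var.REF!r} matches neither panel allele; dropped"
                )
                continue
        if flip:
            obs = col != MISSING
            col[obs] = 2 - col[obs]
        loci.append(locus_id)
        cols.append(col)
    if dropped:
        log.warning("dropped %d VCF sites not in panel: %s", len(dropped), dropped[:5])
    if not loci:
        raise ValueError(f"{path}: no usable sites")
    calls = np.stack(cols, axis=1)
    used_panel = panel.subset(loci) if panel is not None else None
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        calls=calls,
        pops=_check_popmap(samples, pops),
        panel=used_panel,
    )


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the TSV dialect (tokens N/H/F/.)."""
    df = matrix.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_depths(matrix: GenotypeMatrix, path: str | Path) -> None:
    if matrix.depths is None:
        raise ValueError("matrix has no depth table")
    df = pd.DataFrame(matrix.depths, index=matrix.samples, columns=matrix.loci)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# genepop dialect: 2-digit allele codes, native=01, foreign=02, missing 0000
_GENEPOP_CODE = {
    HOM_NATIVE: "0101",
    HET: "0102",
    HOM_FOREIGN: "0202",
    MISSING: "0000",
}


def export_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "introscreen export") -> None:
    """Write the matrix in genepop format, one POP block per population."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(str(locus) + "\n")
        for pop in matrix.populations:
            fh.write("POP\n")
            for i, s in enumerate(matrix.samples):
                if matrix.pops[s] != pop:
                    continue
                codes = " ".join(_GENEPOP_CODE[int(c)] for c in matrix.calls[i])
                fh.write(f"{s} ,  {codes}\n")
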