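"""Readers and writers for the formats the tool touches.

Matrix Market coordinate files are the primary exchange format (native
sparse, language-neutral, 1-based externally); dense delimited text and
a minimal VCF conversion are also supported.  Everything is 0-based
internally.  Matrices are loci×individuals: rows are variants, columns
are samples — transposed input will silently compute locus-similarity,
so orientation is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .errors import CodingError, FormatError
from .rsvd import EigenResult
from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vcf_to_matrix",
    "write_eigenvectors",
    "write_similarity",
    "write_bound_reports",
]


def _infer_coding(values: np.ndarray) -> str:
    uniq = set(np.unique(values))
    if uniq.issubset({0.0, 1.0}):
        return "binary"
    if uniq.issubset({0.0, 1.0, 2.0}):
        return "dosage012"
    raise CodingError(f"matrix values {sorted(uniq)[:6]}… fit neither binary nor dosage012")


def read_matrix(path, fmt: str | None = None, coding: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from Matrix Market (.mtx) or delimited text.

    The coding is inferred (binary iff all values are in {0,1}) unless
    given explicitly; explicit codings are validated, so forcing
    ``binary`` on a dosage file raises a coding error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() in (".mtx", ".mm") else "tsv"
    if fmt not in ("mtx", "tsv"):
        raise FormatError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")
    try:
        if fmt == "mtx":
            mat = sparse.csr_matrix(spio.mmread(path), dtype=np.float64)
        else:
            mat = sparse.csr_matrix(np.atleast_2d(np.loadtxt(path)), dtype=np.float64)
    except (ValueError, OSError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise CodingError(f"{path} contains negative or non-integer entries")
    inferred = _infer_coding(data if data.size else np.array([0.0]))
    if coding is None:
        coding = inferred
    return GenotypeMatrix(mat, coding=coding)  # validates explicit coding


def write_matrix(G: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as Matrix Market coordinate (1-based) format."""
    spio.mmwrite(str(path), sparse.coo_matrix(G.values), field="integer")


def read_vcf_to_matrix(path, mode: str = "binary") -> GenotypeMatrix:
    """Convert the GT fields of a VCF into a loci×individuals matrix.

    Rows follow the file's variant order, columns the sample header
    order.  Multiallelic records are skipped (logged count); missing
    genotypes count as 0 reference-like alleles (logged per site).
    ``mode='dosage'`` stores the alternate-allele count 0/1/2,
    ``mode='binary'`` stores 1 iff any alternate allele is present.
    """
    if mode not in ("binary", "dosage"):
        raise FormatError(f"mode must be 'binary' or 'dosage', got {mode!r}")
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required for VCF input") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"could not open VCF {path}: {exc}") from exc
    m = len(vcf.samples)
    rows: list[np.ndarray] = []
    skipped = 0
    missing_sites = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        gts = variant.genotypes  # [[allele1, allele2, phased], ...]
        if gts is None:
            raise FormatError(f"VCF {path} has no GT field")
        row = np.zeros(m)
        site_missing = 0
        for j, gt in enumerate(gts):
            alleles = [a for a in gt[:-1]]
            site_missing += sum(1 for a in alleles if a < 0)
            alt = sum(1 for a in alleles if a > 0)
            row[j] = min(alt, 2) if mode == "dosage" else float(alt > 0)
        if site_missing:
            missing_sites += 1
            logger.debug("site %s:%s has %d missing alleles (treated as reference)",
                         variant.CHROM, variant.POS, site_missing)
        rows.append(row)
    if skipped:
        logger.warning("skipped %d multiallelic records in %s", skipped, path)
    if missing_sites:
        logger.warning("%d sites in %s had missing genotypes mapped to 0", missing_sites, path)
    if not rows:
        raise FormatError(f"no biallelic records with GT found in {path}")
    dense = np.vstack(rows)
    coding = "binary" if mode == "binary" else "dosage012"
    return GenotypeMatrix(sparse.csr_matrix(dense), coding=coding)


def write_eigenvectors(result: EigenResult, path, labels=None) -> None:
    """Write PCs as TSV (sample, PC1..PCk; 10 significant digits) plus a JSON sidecar.

    The sidecar (``<path>.json``) records eigenvalues, k, q, seed and
    method so any randomized run can be replayed exactly.
    """
    path = Path(path)
    m, k = result.vectors.shape
    if labels is None:
        labels = [str(i + 1) for i in range(m)]
    if len(labels) != m:
        raise FormatError(f"need {m} labels, got {len(labels)}")
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"PC{j+1}" for j in range(k)) + "\n")
        for i in range(m):
            vals = "\t".join(f"{result.vectors[i, j]:.10g}" for j in range(k))
            fh.write(f"{labels[i]}\t{vals}\n")
    sidecar = {
        "eigenvalues": [float(v) for v in result.values],
        "k": result.k,
        "q": result.q,
        "seed": result.seed,
        "method": result.method,
        "degenerate": result.degenerate,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_eigenvectors(path) -> tuple[list[str], np.ndarray]:
    """Read back a PC table written by :func:`write_eigenvectors`."""
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise FormatError(f"{path} is not a PC table (missing header)")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return labels, np.array(rows)


def write_similarity(values: np.ndarray, path) -> None:
    """Write a dense similarity matrix as TSV with a 1-based sample header row."""
    m = values.shape[0]
    with open(path, "w") as fh:
        fh.write("\t".join(str(i + 1) for i in range(m)) + "\n")
        for i in range(m):
            fh.write("\t".join(f"{values[i, j]:.10g}" for j in range(m)) + "\n")


def write_bound_reports(reports, path) -> None:
    """Write bound reports as a TSV table, one row per eigenvector order."""
    cols = ("order", "l2_measured", "angle_bound", "matrix_bound",
            "gap", "norm", "gap_method", "vacuous_flag")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write(
                f"{r.order}\t{r.l2_measured:.10g}\t{r.angle_bound:.10g}\t"
                f"{r.matrix_bound:.10g}\t{r.lambda_gap:.10g}\t{r.norm_used}\t"
                f"{r.gap_method}\t{int(r.vacuous)}\n"
            )
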