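"""File formats: genotype tables, prototype libraries, score tables.

Two genotype dialects are supported:

* ``simple_tsv`` -- header ``sample_id<TAB>phenotype<TAB><snp>...``;
  genotype cells are minor-allele counts 0/1/2 or ``NA``; phenotype is
  0 (control) / 1 (case).
* ``plink_raw`` -- the PLINK ``--recode A`` additive dialect
  (``FID IID PAT MAT SEX PHENOTYPE SNP...``, whitespace separated,
  phenotype 1=control/2=case, ``NA`` for missing).

On read, columns whose control-sample allele frequency exceeds 0.5 are
flipped so the minor allele is counted (recorded on the dataset and in
the log).  Libraries round-trip through JSON with stable key order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, MISSING
from .prototype_selection import PrototypeLibrary

__all__ = [
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_library",
    "write_library",
    "write_scores",
    "file_checksum",
]

logger = logging.getLogger("epiproto")


class GenotypeParseError(ValueError):
    """A genotype file failed validation; carries the offending line."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _parse_count(token: str, path, line_no) -> int:
    if token in ("NA", "na", ""):
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    # plink emits floats for imputed dosages; accept exact integers only
    try:
        val = float(token)
    except ValueError:
        raise GenotypeParseError(path, line_no, f"unknown genotype symbol {token!r}")
    if val in (0.0, 1.0, 2.0):
        return int(val)
    raise GenotypeParseError(path, line_no, f"unknown genotype symbol {token!r}")


def read_genotypes(path, dialect: str = "simple_tsv") -> GenotypeDataset:
    """Parse a genotype table into a :class:`GenotypeDataset`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError(path, 1, "empty file")

    if dialect == "simple_tsv":
        header = lines[0].rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
            raise GenotypeParseError(
                path, 1, "expected header: sample_id, phenotype, <snp>...")
        snp_ids = header[2:]
        meta_cols, pheno_col, pheno_map = 2, 1, {"0": 0, "1": 1}
        sep = "\t"
    elif dialect == "plink_raw":
        header = lines[0].split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise GenotypeParseError(
                path, 1, "expected PLINK .raw header FID IID PAT MAT SEX PHENOTYPE ...")
        snp_ids = header[6:]
        meta_cols, pheno_col, pheno_map = 6, 5, {"1": 0, "2": 1}
        sep = None  # any whitespace
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not snp_ids:
        raise GenotypeParseError(path, 1, "no SNP columns")

    rows, phenos, ids = [], [], []
    seen = set()
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(sep) if sep else line.split()
        if len(fields) != meta_cols + len(snp_ids):
            raise GenotypeParseError(
                path, line_no,
                f"expected {meta_cols + len(snp_ids)} fields, got {len(fields)}")
        sid = fields[0] if dialect == "simple_tsv" else f"{fields[0]}:{fields[1]}"
        if sid in seen:
            raise GenotypeParseError(path, line_no, f"duplicate sample id {sid!r}")
        seen.add(sid)
        ptok = fields[pheno_col]
        if ptok not in pheno_map:
            raise GenotypeParseError(
                path, line_no,
                f"phenotype must be one of {sorted(pheno_map)}, got {ptok!r}")
        ids.append(sid)
        phenos.append(pheno_map[ptok])
        rows.append([_parse_count(t, path, line_no) for t in fields[meta_cols:]])

    if not rows:
        raise GenotypeParseError(path, 2, "no data rows")
    ds = GenotypeDataset(genotypes=np.array(rows, dtype=np.int8),
                         phenotype=np.array(phenos, dtype=np.int8),
                         snp_ids=list(snp_ids))
    if ds.flipped.any():
        flipped = [s for s, f in zip(ds.snp_ids, ds.flipped) if f]
        logger.info("re-oriented %d SNP(s) to minor-allele counting: %s",
                    len(flipped), ", ".join(flipped[:10]))
    return ds


def write_genotypes(path, ds: GenotypeDataset, sample_ids=None) -> None:
    """Write a dataset in the simple TSV dialect."""
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(ds.n_individuals)]
    with path.open("w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(ds.snp_ids) + "\n")
        for sid, pheno, row in zip(sample_ids, ds.phenotype, ds.genotypes):
            cells = "\t".join("NA" if g == MISSING else str(int(g)) for g in row)
            fh.write(f"{sid}\t{int(pheno)}\t{cells}\n")


def write_library(path, library: PrototypeLibrary) -> None:
    """Serialize a prototype library as stably-ordered JSON."""
    Path(path).write_text(
        json.dumps(library.to_dict(), indent=1, sort_keys=True) + "\n")


def read_library(path) -> PrototypeLibrary:
    data = json.loads(Path(path).read_text())
    return PrototypeLibrary.from_dict(data)


def write_scores(path, scores: pd.DataFrame) -> None:
    """Write a ranked-pairs table as TSV (deterministic ordering)."""
    cols = [c for c in ("rank", "round", "snp_i", "snp_j", "snp_i_id", "snp_j_id",
                        "method", "model_id", "chi2", "pvalue")
            if c in scores.columns]
    scores.to_csv(path, sep="\t", index=False, columns=cols,
                  float_format="%.10g")


def file_checksum(path) -> str:
    """Short sha256 digest used in run logs."""
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:12]
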