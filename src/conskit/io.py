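"""VCF, BED and table I/O plus the in-memory genotype container.

Genotypes are held as a dense ``(n_sites, n_samples)`` int8 matrix with the
usual dosage coding: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing.  VCF writing goes through pysam and
reading through cyvcf2, so both ends speak standard VCF 4.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: INFO keys carried through simulation and filtering (all Float).
QC_INFO_KEYS = ("QD", "FS", "MQ", "ReadPosRankSum", "SB")


@dataclass
class GenotypeTable:
    """Samples x biallelic-SNV genotype matrix with per-site QC annotations.

    Sites are ordered by (chromosome, position).  ``info`` is a DataFrame
    aligned with the site arrays carrying the QC floats (NaN when the VCF
    lacked the key) and, when present, an ``ANN`` column of SnpEff-style
    effect strings.  ``n_alt`` records how many ALT alleles the original
    record had; only the first is stored, which is all downstream stages
    need because multi-allelic records are removed by the hard filters.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    info: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    n_alt: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_alt is None:
            self.n_alt = np.ones(len(self.pos), dtype=np.int8)
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeTable":
        """Subset to the given sites (boolean mask or integer index)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            info=self.info.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx],
            dp=self.dp[idx],
            n_alt=self.n_alt[idx],
            chrom_lengths=self.chrom_lengths,
        )

    def genotypes_of(self, name: str) -> np.ndarray:
        return self.gt[:, self.sample_index(name)]


def write_vcf(table: GenotypeTable, path: str | Path) -> Path:
    """Serialize a genotype table to an uncompressed VCF 4.2 file."""
    path = Path(path)
    header = pysam.VariantHeader()
    lengths = table.chrom_lengths or {}
    for name in dict.fromkeys(table.chrom.tolist()):
        header.contigs.add(name, length=lengths.get(name))
    for name, length in lengths.items():
        if name not in header.contigs:
            header.contigs.add(name, length=length)
    for key in QC_INFO_KEYS:
        header.add_meta(
            "INFO", items=[("ID", key), ("Number", 1), ("Type", "Float"), ("Description", f"{key} site annotation")]
        )
    header.add_meta(
        "INFO",
        items=[("ID", "ANN"), ("Number", "."), ("Type", "String"), ("Description", "Functional annotations")],
    )
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"), ("Description", "Read depth")])
    for s in table.samples:
        header.add_sample(s)

    gt_alleles = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    has_ann = "ANN" in table.info.columns
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            rec = out.new_record(
                contig=str(table.chrom[i]),
                start=int(table.pos[i]) - 1,
                stop=int(table.pos[i]),
                alleles=(str(table.ref[i]), str(table.alt[i])),
            )
            rec.qual = float(table.qual[i])
            for key in QC_INFO_KEYS:
                if key in table.info.columns:
                    v = table.info[key].iat[i]
                    if v == v:  # skip NaN
                        rec.info[key] = float(v)
            if has_ann:
                ann = table.info["ANN"].iat[i]
                if isinstance(ann, str) and ann:
                    rec.info["ANN"] = ann
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_alleles[int(table.gt[i, j])]
                rec.samples[s]["DP"] = int(table.dp[i, j])
            out.write(rec)
    return path


def read_vcf(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Multi-allelic records are kept (first ALT only) with ``n_alt`` recording
    the allele count, so the filtering stage can tally their removal.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    n_alt: list[int] = []
    info_rows: dict[str, list] = {key: [] for key in QC_INFO_KEYS}
    ann: list = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    any_ann = False
    for v in vcf:
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        n_alt.append(len(v.ALT))
        for key in QC_INFO_KEYS:
            val = v.INFO.get(key)
            info_rows[key].append(np.nan if val is None else float(val))
        a = v.INFO.get("ANN")
        ann.append(a)
        any_ann = any_ann or a is not None
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gt_rows.append(g)
        d = v.format("DP")
        if d is None:
            dp_rows.append(np.full(len(samples), -1, dtype=np.int32))
        else:
            d = d.astype(np.int32).reshape(-1)
            d[d < 0] = -1
            dp_rows.append(d)
    lengths = dict(chrom_lengths) if chrom_lengths else {}
    if not lengths:
        for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
            if ln:
                lengths[name] = int(ln)
    vcf.close()
    info = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in info_rows.items()})
    if any_ann:
        info["ANN"] = ann
    return GenotypeTable(
        samples=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        info=info,
        gt=np.vstack(gt_rows) if gt_rows else np.zeros((0, len(samples)), dtype=np.int8),
        dp=np.vstack(dp_rows) if dp_rows else np.zeros((0, len(samples)), dtype=np.int32),
        n_alt=np.asarray(n_alt, dtype=np.int8),
        chrom_lengths=lengths or None,
    )


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3 file of 0-based half-open intervals.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: invalid interval [{start}, {end})")
            intervals.append((parts[0], start, end))
    return intervals


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length-in-bp) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, ln in lengths.items():
            fh.write(f"{name}\t{ln}\n")
    return path


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample table (sample, species, population, is_outgroup)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample metadata must contain columns {sorted(required)}")
    if "population" not in df.columns:
        df["population"] = df["species"]
    if "is_outgroup" not in df.columns:
        df["is_outgroup"] = False
    df["is_outgroup"] = df["is_outgroup"].astype(bool)
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
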