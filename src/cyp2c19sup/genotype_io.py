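"""Read and write genotypes for the two CYP2C19 marker SNPs.

The toolkit works from exactly two single-nucleotide polymorphisms:

* rs12248560 (NM_000769.2:c.-806C>T) — the promoter variant tagging the
  gain-of-function star allele CYP2C19*17; alleles C (reference) and T.
* rs4244285 (NM_000769.2:c.681G>A, p.Pro227Pro) — the splice-defect variant
  tagging the loss-of-function star allele CYP2C19*2; alleles G (reference)
  and A.

Genotypes are unphased everywhere: (C,T) and (T,C) are the same genotype.
Phase separators in VCF input are accepted but phase is discarded — the
calling module re-derives phase from the *2/*17 linkage-disequilibrium
assumption. Missing data is tracked per SNP slot, so a sample typed at only
one marker is still representable (and reportable as uncallable).

Marker records in VCF are located by rsID in the ID column. Positional
(chrom/pos) matching is available only through an explicit config override,
because genome builds differ and no build is assumed; the placeholder
coordinates this module writes are not meaningful.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import (
    AlleleDomainError,
    AmbiguousRecordError,
    GenotypeParseError,
)

RSID_17 = "rs12248560"
RSID_2 = "rs4244285"
SUPPORTED_RSIDS = (RSID_17, RSID_2)

#: Allowed alleles per marker; any other base is a domain error.
ALLELE_DOMAIN: Mapping[str, frozenset[str]] = {
    RSID_17: frozenset({"C", "T"}),
    RSID_2: frozenset({"G", "A"}),
}
REF_ALLELE = {RSID_17: "C", RSID_2: "G"}
ALT_ALLELE = {RSID_17: "T", RSID_2: "A"}

#: Placeholder VCF coordinates. The ID column is authoritative for matching;
#: these exist only because the VCF format requires CHROM/POS.
_PLACEHOLDER_CONTIG = "CYP2C19"
_PLACEHOLDER_POS = {RSID_17: 1, RSID_2: 2}

DEFAULT_MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class SnpGenotype:
    """A sample's unphased genotype at one of the two supported markers.

    Alleles are stored reference-allele-first, so two genotypes written in
    different allele orders compare equal. ``allele_a``/``allele_b`` are
    ``None`` exactly when ``missing`` is true.
    """

    rsid: str
    allele_a: str | None
    allele_b: str | None
    missing: bool = False

    def __post_init__(self):
        if self.rsid not in SUPPORTED_RSIDS:
            raise AlleleDomainError(
                f"unsupported rsID {self.rsid!r}; only "
                f"{', '.join(SUPPORTED_RSIDS)} are handled", rsid=self.rsid)
        if self.missing:
            if self.allele_a is not None or self.allele_b is not None:
                raise AlleleDomainError(
                    f"missing genotype at {self.rsid} must carry no alleles",
                    rsid=self.rsid)
            return
        domain = ALLELE_DOMAIN[self.rsid]
        for allele in (self.allele_a, self.allele_b):
            if allele not in domain:
                raise AlleleDomainError(
                    f"allele {allele!r} is outside the domain "
                    f"{sorted(domain)} of {self.rsid}", rsid=self.rsid)
        # normalize to reference-first so unordered genotypes compare equal
        ref = REF_ALLELE[self.rsid]
        a, b = self.allele_a, self.allele_b
        if (a != ref) and (b == ref):
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @classmethod
    def from_alleles(cls, rsid: str, allele_a: str, allele_b: str) -> "SnpGenotype":
        return cls(rsid=rsid, allele_a=allele_a.upper(), allele_b=allele_b.upper())

    @classmethod
    def missing_at(cls, rsid: str) -> "SnpGenotype":
        return cls(rsid=rsid, allele_a=None, allele_b=None, missing=True)

    @property
    def alt_count(self) -> int:
        """Number of variant (non-reference) alleles carried (0, 1 or 2)."""
        if self.missing:
            raise ValueError(f"genotype at {self.rsid} is missing")
        alt = ALT_ALLELE[self.rsid]
        return (self.allele_a == alt) + (self.allele_b == alt)

    def token(self) -> str:
        """Two-character genotype token, e.g. ``CT`` or ``GA``."""
        if self.missing:
            raise ValueError(f"genotype at {self.rsid} is missing")
        return f"{self.allele_a}{self.allele_b}"


@dataclass(frozen=True)
class SampleGenotypes:
    """One sample's genotypes at both markers (either may be missing)."""

    sample_id: str
    g_rs12248560: SnpGenotype
    g_rs4244285: SnpGenotype

    def __post_init__(self):
        if self.g_rs12248560.rsid != RSID_17:
            raise AlleleDomainError(
                f"slot g_rs12248560 holds {self.g_rs12248560.rsid}")
        if self.g_rs4244285.rsid != RSID_2:
            raise AlleleDomainError(
                f"slot g_rs4244285 holds {self.g_rs4244285.rsid}")

    @property
    def callable(self) -> bool:
        """True when both SNP slots carry data (haplogenotype-callable)."""
        return not (self.g_rs12248560.missing or self.g_rs4244285.missing)

    def genotype(self, rsid: str) -> SnpGenotype:
        if rsid == RSID_17:
            return self.g_rs12248560
        if rsid == RSID_2:
            return self.g_rs4244285
        raise AlleleDomainError(f"unsupported rsID {rsid!r}", rsid=rsid)


# ---------------------------------------------------------------------------
# tabular format
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("sample_id", RSID_17, RSID_2)


def _split_table_line(line: str, sep: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\r\n").split(sep)]


def _table_sep(path: str | os.PathLike) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_genotype_table(
    path: str | os.PathLike,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> list[SampleGenotypes]:
    """Read a sample × rsID genotype table (CSV or TSV).

    Expected columns: ``sample_id``, ``rs12248560``, ``rs4244285``.
    Genotype cells are two allele characters in any order (``CT``, ``TC``,
    ``GA``, case-insensitive) or the missing token. Row numbers in error
    messages are 1-based over data rows.
    """
    sep = sep or _table_sep(path)
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file (header expected)")
    header = _split_table_line(lines[0], sep)
    if list(header) != list(_TABLE_COLUMNS):
        unknown = [c for c in header if c not in _TABLE_COLUMNS]
        if unknown:
            raise GenotypeParseError(
                f"{path}: unknown column(s) {unknown}; expected exactly "
                f"{list(_TABLE_COLUMNS)}")
        raise GenotypeParseError(
            f"{path}: columns must be exactly {list(_TABLE_COLUMNS)}, "
            f"got {header}")
    samples: list[SampleGenotypes] = []
    for row_no, line in enumerate(lines[1:], start=1):
        cells = _split_table_line(line, sep)
        if len(cells) != 3:
            raise GenotypeParseError(
                f"{path}: row {row_no}: expected 3 fields, got {len(cells)}")
        sample_id = cells[0]
        gts = []
        for rsid, cell in zip((RSID_17, RSID_2), cells[1:]):
            gts.append(_parse_genotype_token(cell, rsid, missing_token,
                                             path=path, row_no=row_no))
        samples.append(SampleGenotypes(sample_id, gts[0], gts[1]))
    return samples


def _parse_genotype_token(cell: str, rsid: str, missing_token: str,
                          path, row_no: int) -> SnpGenotype:
    token = cell.strip()
    if token.upper() == missing_token.upper() or token == "":
        return SnpGenotype.missing_at(rsid)
    token = token.upper()
    if len(token) != 2 or any(ch not in ALLELE_DOMAIN[rsid] for ch in token):
        raise GenotypeParseError(
            f"{path}: row {row_no}: bad genotype token {cell!r} for {rsid} "
            f"(expected two of {sorted(ALLELE_DOMAIN[rsid])} or "
            f"{missing_token!r})")
    return SnpGenotype.from_alleles(rsid, token[0], token[1])


def write_genotype_table(
    samples: Sequence[SampleGenotypes],
    path: str | os.PathLike,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> None:
    """Write samples as a CSV/TSV genotype table (round-trip safe)."""
    sep = sep or _table_sep(path)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(_TABLE_COLUMNS) + "\n")
        for s in samples:
            cells = [s.sample_id]
            for rsid in (RSID_17, RSID_2):
                g = s.genotype(rsid)
                cells.append(missing_token if g.missing else g.token())
            fh.write(sep.join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF format
# ---------------------------------------------------------------------------

def _record_matches(record, rsid: str,
                    overrides: Mapping[str, Mapping] | None) -> bool:
    if overrides and rsid in overrides:
        ov = overrides[rsid]
        return (record.chrom == str(ov["chrom"])
                and record.pos == int(ov["pos"]))
    if record.id is None:
        return False
    return rsid in record.id.split(";")


def read_vcf(
    path: str | os.PathLike,
    sample_filter: Iterable[str] | None = None,
    config: Mapping | None = None,
) -> list[SampleGenotypes]:
    """Read the two marker genotypes from a VCF (v4.x) file.

    Records are matched by rsID in the ID column; a per-rsID
    ``{"chrom": ..., "pos": ...}`` override may be supplied under
    ``config["positions"]`` for files without rsIDs. A marker with no
    matching record yields a missing genotype for every sample. Multi-allelic
    records are honored allele-by-allele: any genotype referencing an allele
    outside the marker's domain is a data error naming the sample and rsid.
    """
    overrides = (config or {}).get("positions")
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise GenotypeParseError(f"{path}: cannot parse VCF: {exc}") from exc
    with vcf:
        all_samples = list(vcf.header.samples)
        if sample_filter is not None:
            wanted = [s for s in all_samples if s in set(sample_filter)]
        else:
            wanted = all_samples
        per_rsid: dict[str, dict[str, SnpGenotype]] = {}
        for record in vcf:
            for rsid in SUPPORTED_RSIDS:
                if not _record_matches(record, rsid, overrides):
                    continue
                if rsid in per_rsid:
                    raise AmbiguousRecordError(
                        f"{path}: duplicated record for {rsid}")
                per_rsid[rsid] = _genotypes_from_record(record, rsid, wanted)
    out = []
    for sid in wanted:
        g17 = per_rsid.get(RSID_17, {}).get(sid, SnpGenotype.missing_at(RSID_17))
        g2 = per_rsid.get(RSID_2, {}).get(sid, SnpGenotype.missing_at(RSID_2))
        out.append(SampleGenotypes(sid, g17, g2))
    return out


def _genotypes_from_record(record, rsid: str,
                           samples: Sequence[str]) -> dict[str, SnpGenotype]:
    alleles = record.alleles  # (REF, ALT1, ALT2, ...)
    domain = ALLELE_DOMAIN[rsid]
    result: dict[str, SnpGenotype] = {}
    for sid in samples:
        gt = record.samples[sid].get("GT")
        if gt is None or len(gt) == 0 or any(ix is None for ix in gt):
            result[sid] = SnpGenotype.missing_at(rsid)
            continue
        if len(gt) != 2:
            raise GenotypeParseError(
                f"non-diploid GT for sample {sid} at {rsid}")
        bases = []
        for ix in gt:
            base = alleles[ix].upper()
            if base not in domain:
                raise AlleleDomainError(
                    f"sample {sid} at {rsid}: allele {base!r} is outside "
                    f"the domain {sorted(domain)}",
                    sample_id=sid, rsid=rsid)
            bases.append(base)
        result[sid] = SnpGenotype.from_alleles(rsid, bases[0], bases[1])
    return result


def write_vcf(samples: Sequence[SampleGenotypes],
              path: str | os.PathLike) -> None:
    """Write samples to a minimal VCF with rsID-keyed records.

    CHROM/POS are placeholders (the ID column is authoritative); genotypes
    are written unphased.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={_PLACEHOLDER_CONTIG}>")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rsid in SUPPORTED_RSIDS:
            ref, alt = REF_ALLELE[rsid], ALT_ALLELE[rsid]
            rec = vcf.new_record(
                contig=_PLACEHOLDER_CONTIG,
                start=_PLACEHOLDER_POS[rsid] - 1,
                stop=_PLACEHOLDER_POS[rsid],
                alleles=(ref, alt),
                id=rsid,
            )
            index = {ref: 0, alt: 1}
            for s in samples:
                g = s.genotype(rsid)
                if g.missing:
                    rec.samples[s.sample_id]["GT"] = (None, None)
                else:
                    rec.samples[s.sample_id]["GT"] = (
                        index[g.allele_a], index[g.allele_b])
                rec.samples[s.sample_id].phased = False
            vcf.write(rec)


def write_genotype_outputs(
    samples: Sequence[SampleGenotypes],
    format: str,
    path: str | os.PathLike,
    **kwargs,
) -> None:
    """Write validated samples as ``vcf`` or ``table`` (dispatcher)."""
    if format == "vcf":
        write_vcf(samples, path)
    elif format == "table":
        write_genotype_table(samples, path, **kwargs)
    else:
        raise GenotypeParseError(f"unknown output format {format!r}")
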