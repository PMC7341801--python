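"""Readers, writers, and the in-memory data model for the SV pipeline.

Formats handled: SV VCF 4.2 (SVTYPE/SVLEN/END in INFO, GT per sample),
RepeatMasker ``.out`` alignment tables (plus a TSV dialect), BED interval
files, YAML/TSV clade maps, and two-column chromosome-length tables.

Coordinate conventions: VCF records are 1-based inclusive internally;
BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: sentinel dosage for an uncalled ("./.") or half-called genotype
MISSING: int = -1

#: the closed set of SV types that flow through the pipeline
SVTYPES = ("INS", "DEL", "INV")

#: closed repeat-class taxonomy (tandem rolls up simple/low-complexity/
#: satellite/rRNA/tRNA/macrosatellite; interspersed = LTR + LINE/CR1 +
#: SINE + DNA)
REPEAT_CLASSES = ("tandem", "LTR", "LINE/CR1", "SINE", "DNA", "other", "no_match")

TANDEM_KEYWORDS = (
    "simple_repeat",
    "low_complexity",
    "satellite",
    "rrna",
    "trna",
    "macrosatellite",
)


class VCFParseError(ValueError):
    """Raised when a VCF data line cannot be parsed; names the line number."""


@dataclass
class SVRecord:
    """One structural variant: the unit flowing through every filter.

    ``pos``/``end`` are 1-based inclusive. ``svlen`` is the positive length
    magnitude in bp. ``seq`` optionally carries the inserted/deleted allele
    sequence; ``support`` the supporting-read count.
    """

    chrom: str
    pos: int
    id: str
    svtype: str
    svlen: int
    end: int
    seq: str | None = None
    support: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype {self.svtype!r} not in {SVTYPES}")
        if self.svlen < 1:
            raise ValueError(f"svlen must be >= 1, got {self.svlen}")
        if self.svtype in ("DEL", "INV"):
            span = self.end - self.pos + 1
            if abs(span - self.svlen) > 1:
                raise ValueError(
                    f"{self.id}: DEL/INV span {span} inconsistent with svlen {self.svlen}"
                )
        elif self.end not in (self.pos, self.pos + 1):
            raise ValueError(f"{self.id}: INS end must equal pos or pos+1")

    @property
    def interval(self) -> tuple[int, int]:
        """(start, end) 1-based inclusive span on the reference."""
        return self.pos, max(self.pos, self.end)


class GenotypeMatrix:
    """Variants x diploid individuals alt-allele dosage matrix.

    Entries are drawn from {0, 1, 2, MISSING}. MISSING is a first-class
    state and is never imputed here; downstream analyses decide per
    operation how to treat it.
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        individual_ids: Sequence[str],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(variant_ids), len(individual_ids)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(variant_ids)} variants x {len(individual_ids)} individuals"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("variant ids must be unique")
        if len(set(individual_ids)) != len(individual_ids):
            raise ValueError("individual ids must be unique")
        self.variant_ids = list(variant_ids)
        self.individual_ids = list(individual_ids)
        self.dosage = dosage
        self._vindex = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def row(self, variant_id: str) -> np.ndarray:
        return self.dosage[self._vindex[variant_id]]

    def subset_variants(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        idx = [self._vindex[v] for v in ids]
        return GenotypeMatrix(ids, self.individual_ids, self.dosage[idx])

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        pos = {s: j for j, s in enumerate(self.individual_ids)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(self.variant_ids, ids, self.dosage[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variant_ids == other.variant_ids
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.dosage, other.dosage)
        )


def _default_tolerance(clade_size: int) -> int:
    # outgroup error allowance scales with outgroup size: 4 for large
    # (>16 diploids) outgroups, 2 for small ones
    return 4 if clade_size > 16 else 2


class CladeMap:
    """individual -> (population, clade) assignment with per-clade error tolerances."""

    def __init__(
        self,
        assignments: Mapping[str, tuple[str, str]],
        tolerances: Mapping[str, int] | None = None,
    ) -> None:
        if not assignments:
            raise ValueError("clade map is empty")
        self.assignments = dict(assignments)
        clades: dict[str, list[str]] = {}
        for ind, (_pop, clade) in self.assignments.items():
            clades.setdefault(clade, []).append(ind)
        self._clades = clades
        if tolerances is None:
            tolerances = {c: _default_tolerance(len(m)) for c, m in clades.items()}
        else:
            tolerances = dict(tolerances)
            for c in clades:
                tolerances.setdefault(c, _default_tolerance(len(clades[c])))
        if any(t < 0 for t in tolerances.values()):
            raise ValueError("tolerances must be non-negative")
        self.tolerances = tolerances

    @property
    def individuals(self) -> list[str]:
        return list(self.assignments)

    @property
    def clades(self) -> dict[str, list[str]]:
        return {c: list(m) for c, m in self._clades.items()}

    def clade_of(self, individual: str) -> str:
        return self.assignments[individual][1]

    def population_of(self, individual: str) -> str:
        return self.assignments[individual][0]

    def members(self, clade: str) -> list[str]:
        return list(self._clades[clade])

    def tolerance(self, clade: str) -> int:
        return self.tolerances[clade]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CladeMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        assignments: dict[str, tuple[str, str]] = {}
        for ind, entry in doc["individuals"].items():
            if "clade" not in entry:
                raise ValueError(f"individual {ind}: missing clade")
            if ind in assignments:
                raise ValueError(f"duplicate individual {ind}")
            assignments[ind] = (entry.get("population", entry["clade"]), entry["clade"])
        return cls(assignments, doc.get("tolerances"))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CladeMap":
        assignments: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_ind = header.index("individual")
                i_pop = header.index("population")
                i_clade = header.index("clade")
            except ValueError as exc:
                raise ValueError(f"clade map {path}: missing column ({exc})") from None
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                ind = fields[i_ind]
                if ind in assignments:
                    raise ValueError(f"duplicate individual {ind}")
                assignments[ind] = (fields[i_pop], fields[i_clade])
        return cls(assignments)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "individuals": {
                ind: {"population": pop, "clade": clade}
                for ind, (pop, clade) in self.assignments.items()
            },
            "tolerances": dict(self.tolerances),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a clade map from YAML (.yaml/.yml) or TSV."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        return CladeMap.from_yaml(path)
    return CladeMap.from_tsv(path)


@dataclass
class RepeatMatch:
    """One repeat-library alignment hit against a variant's sequence."""

    variant_id: str
    repeat_name: str
    repeat_class: str
    overlap_bp: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"repeat_class {self.repeat_class!r} not in {REPEAT_CLASSES}")
        if self.overlap_bp < 0:
            raise ValueError("overlap_bp must be >= 0")


def classify_repeat_family(class_family: str) -> str:
    """Map a RepeatMasker class/family string onto the closed class taxonomy."""
    s = class_family.lower()
    # interspersed superfamilies take precedence: e.g. SINE/tRNA is a SINE,
    # not a tandem tRNA repeat
    if s.startswith("ltr"):
        return "LTR"
    if s.startswith("line"):
        return "LINE/CR1"
    if s.startswith("sine"):
        return "SINE"
    if s.startswith("dna"):
        return "DNA"
    if any(k in s for k in TANDEM_KEYWORDS):
        return "tandem"
    return "other"


class ChromTable(dict):
    """chromosome name -> length (bp); plain dict with validation."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        if any(v <= 0 for v in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        super().__init__(lengths)

    @property
    def total_length(self) -> int:
        return sum(self.values())


def read_chrom_table(path: str | Path) -> ChromTable:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            lengths[name] = int(length)
    return ChromTable(lengths)


def write_chrom_table(table: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in table.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _prescan_vcf(path: Path) -> None:
    """Cheap structural validation so parse errors can name a line number."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                n_cols = len(line.rstrip("\n").split("\t"))
                continue
            fields = line.rstrip("\n").split("\t")
            if n_cols is not None and len(fields) != n_cols:
                raise VCFParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            if len(fields) < 8:
                raise VCFParseError(f"{path}:{lineno}: fewer than 8 VCF columns")
            try:
                int(fields[1])
            except ValueError:
                raise VCFParseError(f"{path}:{lineno}: POS {fields[1]!r} is not an integer")


def read_sv_vcf(path: str | Path) -> tuple[list[SVRecord], GenotypeMatrix, Counter]:
    """Read an SV VCF into records plus an alt-allele dosage matrix.

    Records whose SVTYPE is outside {INS, DEL, INV} (e.g. BND, DUP) are
    skipped; the returned Counter tallies them by type. "0/1" and "1/0"
    both map to dosage 1; "./." and half-calls like "./1" map to MISSING.
    Multi-allelic records are rejected: split them upstream.
    """
    path = Path(path)
    _prescan_vcf(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: no sample columns; genotypes are required")
    records: list[SVRecord] = []
    rows: list[list[int]] = []
    skipped: Counter = Counter()
    for i, v in enumerate(vcf):
        svtype = v.INFO.get("SVTYPE")
        if svtype not in SVTYPES:
            skipped[svtype or "no_SVTYPE"] += 1
            continue
        if v.ALT is not None and len(v.ALT) > 1:
            raise ValueError(f"{path}: record {v.ID or i} is multi-allelic; split upstream")
        pos = v.POS
        end = v.end if v.end is not None else pos
        seq = v.INFO.get("SEQ")
        if seq is None:
            alt = v.ALT[0] if v.ALT else ""
            if svtype == "INS" and alt and not alt.startswith("<"):
                seq = alt[1:] if len(alt) > 1 else None
            elif svtype == "DEL" and len(v.REF) > 1:
                seq = v.REF[1:]
        svlen = v.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svtype == "INS":
            # INS length from |SVLEN|, falling back to the allele sequence
            if svlen is not None:
                svlen = abs(int(svlen))
            elif seq:
                svlen = len(seq)
            else:
                raise ValueError(f"{path}: INS record {v.ID or i} lacks SVLEN and SEQ")
            end = pos
        else:
            # DEL/INV length from END-POS (symbolic-allele convention),
            # falling back to |SVLEN|; internal end is 1-based inclusive
            svlen = int(end) - pos if end > pos else abs(int(svlen or 1))
            if svlen < 1:
                svlen = 1
            end = pos + svlen - 1
        support = v.INFO.get("SUPPORT")
        if support is None:
            support = v.INFO.get("RE")
        vid = v.ID or f"{v.CHROM}_{pos}_{svtype}"
        records.append(
            SVRecord(
                chrom=v.CHROM,
                pos=pos,
                id=vid,
                svtype=svtype,
                svlen=int(svlen),
                end=int(end),
                seq=seq,
                support=int(support) if support is not None else None,
            )
        )
        row = []
        for gt in v.genotypes:
            alleles = gt[:-1]
            if len(alleles) < 2 or any(a is None or a < 0 for a in alleles):
                row.append(MISSING)
            else:
                row.append(int(alleles[0] > 0) + int(alleles[1] > 0))
        rows.append(row)
    if skipped:
        logger.info("skipped %d non-{INS,DEL,INV} records: %s", sum(skipped.values()), dict(skipped))
    dosage = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix([r.id for r in records], samples, dosage)
    return records, matrix, skipped


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_sv_vcf(
    records: Sequence[SVRecord],
    genotypes: GenotypeMatrix,
    path: str | Path,
) -> None:
    """Write records + genotypes as VCF 4.2 (symbolic ALTs, SEQ in INFO).

    ``read_sv_vcf`` inverts this writer exactly (records and dosage matrix
    round-trip). Records and matrix rows must be aligned by id.
    """
    ids = [r.id for r in records]
    if ids != genotypes.variant_ids:
        raise ValueError("record ids and genotype-matrix variant ids do not align")
    contig_max: dict[str, int] = {}
    for r in records:
        contig_max[r.chrom] = max(contig_max.get(r.chrom, 0), r.end, r.pos + r.svlen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svclade\n")
        for chrom, length in contig_max.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=SEQ,Number=1,Type=String,Description="Variant allele sequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for r, row in zip(records, genotypes.dosage):
            svlen = -r.svlen if r.svtype == "DEL" else r.svlen
            end_out = r.pos if r.svtype == "INS" else r.pos + r.svlen
            info = f"SVTYPE={r.svtype};SVLEN={svlen};END={end_out}"
            if r.support is not None:
                info += f";SUPPORT={r.support}"
            if r.seq:
                info += f";SEQ={r.seq}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in row)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\tN\t<{r.svtype}>\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Repeat tables
# ---------------------------------------------------------------------------

def read_repeat_table(path: str | Path) -> list[RepeatMatch]:
    """Read repeat matches from RepeatMasker ``.out`` or the TSV dialect.

    The ``.out`` dialect is detected by its banner line ("SW ..."/"score ...");
    it carries three header lines before whitespace-delimited alignment rows.
    overlap_bp is the query-interval length (end - begin + 1). Rows with
    negative coordinates are rejected with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first = next((ln for ln in lines if ln.strip()), "")
    if first.split()[:1] in (["SW"], ["score"]):
        return _parse_rm_out(lines, path)
    return _parse_repeat_tsv(lines, path)


def _parse_rm_out(lines: list[str], path: Path) -> list[RepeatMatch]:
    matches: list[RepeatMatch] = []
    body = lines[3:]  # two banner lines + one blank
    for ln in body:
        if not ln.strip():
            continue
        f = ln.split()
        score = float(f[0])
        qname, qbegin, qend = f[4], int(f[5]), int(f[6])
        if qbegin < 0 or qend < 0 or qend < qbegin:
            warnings.warn(f"{path}: rejected row with bad query interval [{qbegin},{qend}]")
            continue
        repeat_name, class_family = f[9], f[10]
        matches.append(
            RepeatMatch(
                variant_id=qname,
                repeat_name=repeat_name,
                repeat_class=classify_repeat_family(class_family),
                overlap_bp=qend - qbegin + 1,
                score=score,
            )
        )
    return matches


def _parse_repeat_tsv(lines: list[str], path: Path) -> list[RepeatMatch]:
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    required = ("variant_id", "repeat_name", "repeat_class", "overlap_bp")
    if any(c not in header for c in required):
        raise ValueError(f"{path}: repeat TSV needs columns {required}")
    idx = {c: header.index(c) for c in header}
    matches: list[RepeatMatch] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.rstrip("\n").split("\t")
        overlap = int(f[idx["overlap_bp"]])
        if overlap < 0:
            warnings.warn(f"{path}: rejected row with negative overlap")
            continue
        matches.append(
            RepeatMatch(
                variant_id=f[idx["variant_id"]],
                repeat_name=f[idx["repeat_name"]],
                repeat_class=f[idx["repeat_class"]],
                overlap_bp=overlap,
                score=float(f[idx["score"]]) if "score" in idx else 0.0,
            )
        )
    return matches


def write_repeat_table(matches: Iterable[RepeatMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\trepeat_name\trepeat_class\toverlap_bp\tscore\n")
        for m in matches:
            fh.write(f"{m.variant_id}\t{m.repeat_name}\t{m.repeat_class}\t{m.overlap_bp}\t{m.score}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) as (chrom, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
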