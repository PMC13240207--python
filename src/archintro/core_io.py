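"""Data model and readers/writers for the standard formats the pipeline touches.

Coordinate conventions: variant positions are 1-based inclusive (VCF);
masks are half-open 0-based intervals (BED). Conversion between the two
happens exactly once, at read/write time.

Allele encoding in :class:`HaplotypePanel` matrices:

* ``0`` / ``1`` — reference / alternate allele
* ``MISSING`` (−1) — no call
* ``HET`` (−2) — heterozygous archaic genotype collapsed onto its single
  pseudo-haplotype row (archaics are unphased; each contributes one row)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
HET = -2

MODERN_CARRIER = "modern_carrier"
MODERN_NONCARRIER = "modern_noncarrier"
ARCHAIC = "archaic"
ANCESTRAL = "ancestral"

_GROUPS = {MODERN_CARRIER, MODERN_NONCARRIER, ARCHAIC, ANCESTRAL}

_ARCHAIC_HEADER_KEY = "##archaic_samples="


class UnphasedGenotypeError(ValueError):
    """A modern sample carries an unphased genotype."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant position.

    ``ancestral_state`` records which allele is ancestral (``"ref"``,
    ``"alt"`` or ``"unknown"``). Multiallelic records survive reading but
    are flagged so :func:`filter_sites` can drop them.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    ancestral_state: str = "unknown"
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.ancestral_state not in ("ref", "alt", "unknown"):
            raise ValueError(f"bad ancestral_state {self.ancestral_state!r}")

    @property
    def ancestral_allele(self) -> str | None:
        if self.ancestral_state == "ref":
            return self.ref_allele
        if self.ancestral_state == "alt":
            return self.alt_allele
        return None


@dataclass
class HaplotypePanel:
    """Phased allele matrix (haplotypes × sites) with per-haplotype groups."""

    haplotype_ids: list[str]
    alleles: np.ndarray
    sites: list[VariantSite]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes x sites)")
        n_hap, n_sites = self.alleles.shape
        if len(self.haplotype_ids) != n_hap:
            raise ValueError("haplotype_ids length does not match allele matrix")
        if len(self.group_labels) != n_hap:
            raise ValueError("group_labels length does not match allele matrix")
        if len(self.sites) != n_sites:
            raise ValueError("sites length does not match allele matrix")
        bad = set(self.group_labels) - _GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("sites must be strictly increasing by (chrom, pos)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def indices_for(self, *groups: str) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.group_labels) if g in groups], dtype=np.intp
        )

    def column(self, site_index: int) -> np.ndarray:
        return self.alleles[:, site_index]

    def site_index(self, pos: int, chrom: str | None = None) -> int:
        for i, s in enumerate(self.sites):
            if s.pos == pos and (chrom is None or s.chrom == chrom):
                return i
        raise KeyError(f"no site at position {pos}")

    def subset_sites(self, indices: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(
            haplotype_ids=list(self.haplotype_ids),
            alleles=self.alleles[:, idx],
            sites=[self.sites[i] for i in idx],
            group_labels=list(self.group_labels),
        )

    def subset_haplotypes(self, ids: Iterable[str]) -> "HaplotypePanel":
        wanted = list(ids)
        lookup = {h: i for i, h in enumerate(self.haplotype_ids)}
        idx = [lookup[h] for h in wanted]
        return HaplotypePanel(
            haplotype_ids=wanted,
            alleles=self.alleles[idx, :],
            sites=list(self.sites),
            group_labels=[self.group_labels[i] for i in idx],
        )

    def with_groups(self, mapping: dict[str, str]) -> "HaplotypePanel":
        """Return a copy with group labels replaced for the listed haplotype ids."""
        labels = [mapping.get(h, g) for h, g in zip(self.haplotype_ids, self.group_labels)]
        return HaplotypePanel(
            haplotype_ids=list(self.haplotype_ids),
            alleles=self.alleles.copy(),
            sites=list(self.sites),
            group_labels=labels,
        )


@dataclass
class GeneticMap:
    """Monotone physical-position → cumulative-cM lookup (single chromosome)."""

    positions: np.ndarray
    cumulative_cM: np.ndarray
    chrom: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=np.float64)
        if self.positions.shape != self.cumulative_cM.shape or self.positions.ndim != 1:
            raise ValueError("positions and cumulative_cM must be 1-D and equal length")
        if self.positions.size < 2:
            raise ValueError("genetic map needs at least two anchor points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise ValueError("cumulative cM must be nondecreasing")

    def cm_at(self, pos) -> np.ndarray | float:
        """Cumulative cM at physical position(s); linear interpolation, no extrapolation."""
        p = np.asarray(pos, dtype=np.float64)
        if np.any(p < self.positions[0]) or np.any(p > self.positions[-1]):
            raise ValueError(
                f"position outside map range [{self.positions[0]:.0f}, {self.positions[-1]:.0f}]"
            )
        out = np.interp(p, self.positions, self.cumulative_cM)
        return float(out) if np.isscalar(pos) else out

    def cm_between(self, pos_a: int, pos_b: int) -> float:
        lo, hi = sorted((pos_a, pos_b))
        return float(self.cm_at(hi) - self.cm_at(lo))


@dataclass
class RegionMask:
    """Accessibility mask: half-open 0-based [start, end) intervals per chromosome."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {c: _normalize_intervals(iv) for c, iv in self.intervals.items()}

    def contains(self, chrom: str, pos_1based: int) -> bool:
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return False
        p = pos_1based - 1  # to 0-based
        i = np.searchsorted(iv[:, 0], p, side="right") - 1
        return i >= 0 and p < iv[i, 1]

    def total_span(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


def _normalize_intervals(intervals) -> np.ndarray:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    if np.any(iv[:, 1] < iv[:, 0]):
        raise ValueError("interval end before start")
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [iv[0].copy()]
    for start, end in iv[1:]:
        if start <= merged[-1][1]:  # overlapping or touching
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([start, end]))
    return np.array(merged, dtype=np.int64)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def _parse_region(region: str | None):
    if region is None:
        return None
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, None, None
    start, _, end = span.partition("-")
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    archaic_samples: Sequence[str] | None = None,
) -> HaplotypePanel:
    """Read a (possibly merged modern+archaic) VCF into a :class:`HaplotypePanel`.

    Modern samples must be phased; each contributes two haplotype rows
    (``<sample>_1``, ``<sample>_2``) in phase order. Archaic samples are
    unphased and contribute one pseudo-haplotype row each: homozygous calls
    map to 0/1, heterozygous calls to the ``HET`` code, no-calls to
    ``MISSING``. Which samples are archaic is taken from ``archaic_samples``
    or, failing that, from an ``##archaic_samples=`` header line.

    Multiallelic records are retained (first ALT kept) and flagged so that
    :func:`filter_sites` can remove them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        if archaic_samples is None:
            archaic_samples = []
            for line in vcf.raw_header.splitlines():
                if line.startswith(_ARCHAIC_HEADER_KEY):
                    value = line[len(_ARCHAIC_HEADER_KEY):].strip()
                    archaic_samples = [s for s in value.split(",") if s]
        archaic_set = set(archaic_samples)
        samples = list(vcf.samples)

        hap_ids: list[str] = []
        groups: list[str] = []
        row_of_sample: dict[str, int] = {}
        for s in samples:
            row_of_sample[s] = len(hap_ids)
            if s in archaic_set:
                hap_ids.append(s)
                groups.append(ARCHAIC)
            else:
                hap_ids.extend([f"{s}_1", f"{s}_2"])
                groups.extend([MODERN_NONCARRIER, MODERN_NONCARRIER])

        want = _parse_region(region)
        sites: list[VariantSite] = []
        columns: list[np.ndarray] = []
        for v in vcf:
            if want is not None:
                chrom, start, end = want
                if v.CHROM != chrom:
                    continue
                if start is not None and not (start <= v.POS <= end):
                    continue
            multi = len(v.ALT) > 1
            alt = v.ALT[0] if v.ALT else "."
            aa = v.INFO.get("AA")
            if aa is None:
                anc = "unknown"
            elif str(aa).upper() == v.REF.upper():
                anc = "ref"
            elif str(aa).upper() == alt.upper():
                anc = "alt"
            else:
                anc = "unknown"
            site = VariantSite(
                chrom=v.CHROM,
                pos=v.POS,
                id=v.ID or ".",
                ref_allele=v.REF,
                alt_allele=alt,
                ancestral_state=anc,
                multiallelic=multi,
            )
            col = np.full(len(hap_ids), MISSING, dtype=np.int8)
            for s, gt in zip(samples, v.genotypes):
                a0, a1, phased = gt[0], gt[1], bool(gt[-1])
                r = row_of_sample[s]
                if s in archaic_set:
                    if a0 < 0 or a1 < 0:
                        col[r] = MISSING
                    elif a0 == a1:
                        col[r] = min(a0, 1)  # collapse >1 alleles of multiallelics onto alt
                    else:
                        col[r] = HET
                else:
                    if not phased:
                        raise UnphasedGenotypeError(
                            f"unphased genotype for sample {s!r} at {v.CHROM}:{v.POS}"
                        )
                    col[r] = MISSING if a0 < 0 else min(a0, 1)
                    col[r + 1] = MISSING if a1 < 0 else min(a1, 1)
            sites.append(site)
            columns.append(col)
    finally:
        vcf.close()

    alleles = (
        np.stack(columns, axis=1) if columns else np.empty((len(hap_ids), 0), dtype=np.int8)
    )
    return HaplotypePanel(hap_ids, alleles, sites, groups)


def write_vcf(panel: HaplotypePanel, path: str | Path, contig_length: int | None = None) -> None:
    """Write a panel as an uncompressed VCF 4.2 file.

    Modern haplotype pairs (``x_1``/``x_2``) become one phased diploid
    sample; archaic pseudo-haplotype rows become one unphased diploid
    sample (HET → ``0/1``). Ancestral states go to the ``AA`` INFO field,
    archaic sample names to an ``##archaic_samples=`` header line.
    """
    samples: list[tuple[str, str, tuple[int, ...]]] = []  # (name, kind, row indices)
    i = 0
    while i < panel.n_haplotypes:
        if panel.group_labels[i] == ARCHAIC:
            samples.append((panel.haplotype_ids[i], ARCHAIC, (i,)))
            i += 1
        else:
            hid = panel.haplotype_ids[i]
            if not hid.endswith("_1") or i + 1 >= panel.n_haplotypes:
                raise ValueError(f"modern haplotypes must come in _1/_2 pairs (at {hid!r})")
            name = hid[:-2]
            if panel.haplotype_ids[i + 1] != f"{name}_2":
                raise ValueError(f"modern haplotypes must come in _1/_2 pairs (at {hid!r})")
            samples.append((name, "modern", (i, i + 1)))
            i += 2

    archaic_names = [n for n, kind, _ in samples if kind == ARCHAIC]
    chroms = {s.chrom for s in panel.sites}
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in sorted(chroms):
        if contig_length is not None:
            lines.append(f"##contig=<ID={c},length={contig_length}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    if archaic_names:
        lines.append(_ARCHAIC_HEADER_KEY + ",".join(archaic_names))
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(n for n, _, _ in samples)
    )

    def code_to_str(a: int) -> str:
        return "." if a == MISSING else str(a)

    for j, site in enumerate(panel.sites):
        aa = site.ancestral_allele
        info = f"AA={aa}" if aa else "."
        fields = [
            site.chrom,
            str(site.pos),
            site.id,
            site.ref_allele,
            site.alt_allele,
            ".",
            "PASS",
            info,
            "GT",
        ]
        for _, kind, rows in samples:
            if kind == ARCHAIC:
                a = int(panel.alleles[rows[0], j])
                if a == HET:
                    fields.append("0/1")
                elif a == MISSING:
                    fields.append("./.")
                else:
                    fields.append(f"{a}/{a}")
            else:
                a0 = int(panel.alleles[rows[0], j])
                a1 = int(panel.alleles[rows[1], j])
                fields.append(f"{code_to_str(a0)}|{code_to_str(a1)}")
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------


def filter_sites(
    panel: HaplotypePanel,
    mask: RegionMask | None = None,
    drop_archaic_hets: bool = True,
) -> HaplotypePanel:
    """Apply the merged-panel site filters.

    A site is retained iff it is biallelic, inside the mask (when given),
    has no missing call in any haplotype, is segregating across the merged
    panel, and — when ``drop_archaic_hets`` — no archaic pseudo-haplotype
    is heterozygous there. Site order is preserved; the operation is
    idempotent.
    """
    if panel.n_sites == 0:
        return panel
    A = panel.alleles
    keep = np.ones(panel.n_sites, dtype=bool)

    keep &= ~np.array([s.multiallelic for s in panel.sites])
    if mask is not None:
        keep &= np.array([mask.contains(s.chrom, s.pos) for s in panel.sites])
    keep &= ~np.any(A == MISSING, axis=0)
    if drop_archaic_hets:
        keep &= ~np.any(A == HET, axis=0)
    # segregating on the merged panel (ignore remaining special codes)
    valid = A >= 0
    has_ref = np.any((A == 0) & valid, axis=0)
    has_alt = np.any((A == 1) & valid, axis=0)
    keep &= has_ref & has_alt

    return panel.subset_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------


def haplotypes_to_fasta(panel: HaplotypePanel, path: str | Path | None = None):
    """Export each haplotype as a sequence of its allele bases, in site order.

    Returns Biopython ``SeqRecord`` objects; writes a FASTA file when
    ``path`` is given. The panel must be missing-free.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    ref = np.array([s.ref_allele for s in panel.sites])
    alt = np.array([s.alt_allele for s in panel.sites])
    records = []
    for i, hid in enumerate(panel.haplotype_ids):
        row = panel.alleles[i]
        if np.any(row < 0):
            raise ValueError(f"haplotype {hid!r} has missing/het calls; filter first")
        seq = "".join(np.where(row == 0, ref, alt))
        records.append(SeqRecord(Seq(seq), id=hid, description=""))
    if path is not None:
        with open(path, "w") as fh:
            seqio_write(records, fh, "fasta")
    return records


# ---------------------------------------------------------------------------
# TSV / BED readers and writers
# ---------------------------------------------------------------------------


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a TSV genetic map with columns (chrom, pos, cumulative_cM)."""
    df = _read_table(path, ["chrom", "pos", "cumulative_cM"])
    chroms = df["chrom"].astype(str).unique()
    if len(chroms) != 1:
        raise ValueError(f"genetic map must cover a single chromosome, got {list(chroms)}")
    return GeneticMap(
        positions=df["pos"].to_numpy(dtype=np.float64),
        cumulative_cM=df["cumulative_cM"].to_numpy(dtype=np.float64),
        chrom=str(chroms[0]),
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": gmap.chrom or ".",
            "pos": gmap.positions.astype(np.int64),
            "cumulative_cM": gmap.cumulative_cM,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_mask(path: str | Path) -> RegionMask:
    """Read a BED3 accessibility mask (0-based half-open)."""
    intervals: dict[str, list[list[int]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        intervals.setdefault(chrom, []).append([start, end])
    return RegionMask({c: np.array(iv, dtype=np.int64) for c, iv in intervals.items()})


def write_mask(mask: RegionMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for start, end in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_fragments(path: str | Path) -> np.ndarray:
    """Read a one-column TSV of fragment genetic lengths (cM)."""
    df = _read_table(path, ["length_cM"])
    lengths = df["length_cM"].to_numpy(dtype=np.float64)
    if np.any(lengths < 0):
        raise ValueError("negative fragment length")
    return lengths


def write_fragments(lengths: Sequence[float] | np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"length_cM": np.asarray(lengths, dtype=np.float64)}).to_csv(
        path, sep="\t", index=False
    )


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    """Read a TSV with or without a header row; assign canonical column names."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.strip() else ""
    tokens = first.split("\t")
    has_header = any(not _is_number(t) for t in tokens[1:]) if len(tokens) > 1 else (
        not _is_number(first.strip())
    )
    df = pd.read_csv(io.StringIO(text), sep="\t", header=0 if has_header else None)
    if df.shape[1] < len(columns):
        raise ValueError(
            f"{path}: expected at least {len(columns)} columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    return df


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
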