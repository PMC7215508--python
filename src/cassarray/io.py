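"""Standard-format readers and writers.

Internal coordinates are 0-based half-open everywhere; conversion to
GFF3 (1-based inclusive) and from/to BED (0-based half-open) happens
only here, at the format boundary.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .elements import TandemArray
from .pcr import Ladder, Primer
from .quant import DilutionPoint, DotBlotMeasurement
from .queries import ArrayHit, ChainHit
from .sequences import MatchSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "GffRecord",
    "read_gff3",
    "write_gff3",
    "chains_to_gff",
    "arrays_to_gff",
    "tandem_arrays_to_gff",
    "sites_to_bed",
    "write_bed",
    "chains_to_table",
    "arrays_to_table",
    "ladder_to_table",
    "read_primers",
    "read_dilution_series",
    "read_dot_blot",
]

GFF_VERSION_LINE = "##gff-version 3"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, wrapped or single-line) FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


@dataclass(frozen=True)
class GffRecord:
    """One GFF3 feature line, held in internal (0-based half-open) coordinates."""

    seqid: str
    source: str
    ftype: str
    start: int     # 0-based inclusive
    end: int       # exclusive
    score: str
    strand: str
    attributes: dict[str, str]

    def to_line(self) -> str:
        attrs = ";".join(
            f"{k}={urllib.parse.quote(v, safe=' ')}" for k, v in self.attributes.items()
        )
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.start + 1),  # GFF3 is 1-based inclusive
                str(self.end),
                self.score,
                self.strand,
                ".",
                attrs or ".",
            ]
        )


def write_gff3(path: str | Path, records: Iterable[GffRecord], header: Sequence[str] = ()) -> None:
    lines = [GFF_VERSION_LINE, *header]
    lines += [r.to_line() for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Light GFF3 reader; coordinates converted back to 0-based half-open."""
    out: list[GffRecord] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        f = raw.split("\t")
        attrs = {}
        if f[8] != ".":
            for item in f[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = urllib.parse.unquote(v)
        out.append(
            GffRecord(f[0], f[1], f[2], int(f[3]) - 1, int(f[4]), f[5], f[6], attrs)
        )
    return out


_SOURCE = "cassarray"


def chains_to_gff(chains: Sequence[ChainHit], motif_names: Sequence[str] | None = None) -> list[GffRecord]:
    """Chain hits as ``linked_match`` features with child ``motif_match`` sites."""
    out: list[GffRecord] = []
    for i, chain in enumerate(chains):
        cid = f"chain{i + 1}"
        out.append(
            GffRecord(
                chain.seq_id, _SOURCE, "linked_match",
                chain.span_start, chain.span_end, str(chain.total_mismatches),
                chain.strand, {"ID": cid, "mismatches": str(chain.total_mismatches)},
            )
        )
        for j, site in enumerate(chain.motif_sites):
            name = motif_names[j] if motif_names else f"motif{j + 1}"
            out.append(
                GffRecord(
                    chain.seq_id, _SOURCE, "motif_match",
                    site.start, site.end, str(site.mismatches), chain.strand,
                    {"ID": f"{cid}.{name}", "Parent": cid, "Name": name},
                )
            )
    return out


def arrays_to_gff(arrays: Sequence[ArrayHit]) -> list[GffRecord]:
    """Array hits as ``tandem_array`` features with child ``linked_match`` units."""
    out: list[GffRecord] = []
    for i, arr in enumerate(arrays):
        aid = f"array{i + 1}"
        out.append(
            GffRecord(
                arr.seq_id, _SOURCE, "tandem_array",
                arr.span_start, arr.span_end, ".", arr.strand,
                {"ID": aid, "n_units": str(arr.n_units)},
            )
        )
        for j, chain in enumerate(arr.unit_chains):
            out.append(
                GffRecord(
                    arr.seq_id, _SOURCE, "linked_match",
                    chain.span_start, chain.span_end,
                    str(chain.total_mismatches), arr.strand,
                    {"ID": f"{aid}.unit{j + 1}", "Parent": aid},
                )
            )
    return out


def tandem_arrays_to_gff(tarrays: Sequence[TandemArray]) -> list[GffRecord]:
    """Decomposed arrays as ``repeat_region`` with LTR / internal children."""
    out: list[GffRecord] = []
    for i, ta in enumerate(tarrays):
        rid = f"repeat{i + 1}"
        lo = min(s for _, s, _ in ta.segments)
        hi = max(e for _, _, e in ta.segments)
        out.append(
            GffRecord(
                ta.seq_id, _SOURCE, "repeat_region", lo, hi, ".", ta.strand,
                {"ID": rid, "n_ltrs": str(ta.n_ltrs), "n_internal": str(ta.n_internal)},
            )
        )
        for j, (kind, s, e) in enumerate(ta.segments):
            ftype = "long_terminal_repeat" if kind == "LTR" else "retrotransposon_internal_region"
            out.append(
                GffRecord(
                    ta.seq_id, _SOURCE, ftype, s, e, ".", ta.strand,
                    {"ID": f"{rid}.{j + 1}", "Parent": rid},
                )
            )
    return out


def sites_to_bed(sites: Sequence[MatchSite], name: str = "site") -> list[str]:
    """Match sites as BED6 lines (0-based half-open, strand column)."""
    return [
        "\t".join(
            [s.seq_id, str(s.start), str(s.end), f"{name}{i + 1}", str(s.mismatches), s.strand]
        )
        for i, s in enumerate(sites)
    ]


def write_bed(path: str | Path, lines: Sequence[str]) -> None:
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def chains_to_table(chains: Sequence[ChainHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in chains],
            "strand": [c.strand for c in chains],
            "span_start": [c.span_start for c in chains],
            "span_end": [c.span_end for c in chains],
            "span_length": [c.span_length for c in chains],
            "mismatches": [c.total_mismatches for c in chains],
        }
    )


def arrays_to_table(arrays: Sequence[ArrayHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [a.seq_id for a in arrays],
            "strand": [a.strand for a in arrays],
            "n_units": [a.n_units for a in arrays],
            "span_start": [a.span_start for a in arrays],
            "span_end": [a.span_end for a in arrays],
            "inter_unit_gaps": [",".join(map(str, a.inter_unit_gaps)) for a in arrays],
        }
    )


def ladder_to_table(ladder: Ladder) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rung": range(1, len(ladder.lengths) + 1),
            "length": ladder.lengths,
            "junctions_spanned": [a.junctions_spanned for a in ladder.amplicons],
        }
    )


def read_primers(path: str | Path) -> list[Primer]:
    """Primers from TSV (id, sequence columns) or FASTA."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [Primer(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "sequence" not in cols:
        # headerless two-column table
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected 'id' and 'sequence' columns")
        return [Primer(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]
    return [
        Primer(str(row[cols["id"]]), str(row[cols["sequence"]]))
        for _, row in df.iterrows()
    ]


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> dict[str, str]:
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return cols


def read_dilution_series(path: str | Path) -> list[DilutionPoint]:
    """TSV with ``concentration`` and ``ct`` columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = _require_columns(df, ["concentration", "ct"], path)
    return [
        DilutionPoint(float(r[cols["concentration"]]), float(r[cols["ct"]]))
        for _, r in df.iterrows()
    ]


def read_dot_blot(path: str | Path) -> DotBlotMeasurement:
    """Single-row TSV with the dot-blot measurement fields."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = [
        "genomic_cpm", "genomic_ng", "fragment_copies",
        "fragment_cpm", "probe_len", "genome_size",
    ]
    cols = _require_columns(df, needed, path)
    row = df.iloc[0]
    return DotBlotMeasurement(
        genomic_cpm=float(row[cols["genomic_cpm"]]),
        genomic_ng=float(row[cols["genomic_ng"]]),
        fragment_copies=float(row[cols["fragment_copies"]]),
        fragment_cpm=float(row[cols["fragment_cpm"]]),
        probe_len=int(row[cols["probe_len"]]),
        genome_size=float(row[cols["genome_size"]]),
    )
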