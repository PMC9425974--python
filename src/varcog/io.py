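"""Readers and writers for the formats the toolkit touches.

Aligned FASTA (families with genome-labeled records), plain nucleotide
FASTA, Newick trees, TSV tables, BED-like interval tables.  All coordinates
in outputs are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .geometry import EmbeddingResult
from .msr import MsrAnnotation
from .scoring import SCORED, FamilyAlignment, HomogeneityProfile
from .variability import CladeContext, VariabilityRecord

__all__ = [
    "RunConfig",
    "parse_genome_id",
    "read_alignment_fasta",
    "read_nucleotide_fasta",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_variability_tsv",
    "write_distance_tsv",
    "write_embedding_tsv",
    "write_membership_tsv",
    "write_msr_bed",
    "write_msr_fraction_tsv",
]


@dataclass
class RunConfig:
    """Effective configuration of a run; defaults are the standard constants."""

    matrix_path: str | None = None  # None -> built-in BLOSUM62
    background_path: str | None = None  # None -> built-in Robinson table
    conserved_max: float = 0.5
    variable_min: float = 2.0
    min_sequences: int = 8
    min_columns: int = 60
    smoothing_bandwidth: float = 20.0
    density_grid: int = 101
    msr_alpha: float = 1e-6
    msr_window_cap: int = 1000
    msr_min_window: int = 80
    msr_k_max: int = 6
    seed: int = 0
    genome_token: str = "genome="

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def parse_genome_id(header: str, token: str = "genome=") -> str:
    """Extract the genome id from a FASTA record header.

    The default rule looks for a ``genome=<id>`` token; failing that, the
    token after the last '|' is used.  Headers matching neither rule raise,
    naming the record.
    """
    m = re.search(re.escape(token) + r"(\S+)", header)
    if m:
        return m.group(1)
    if "|" in header:
        tail = header.rsplit("|", 1)[1].split()[0]
        if tail:
            return tail
    raise ValueError(
        f"cannot parse a genome id from record header {header!r} "
        f"(expected a {token!r} token or a trailing '|<genome>' field)"
    )


def read_alignment_fasta(
    path: str | Path,
    genome_token: str = "genome=",
    family_id: str | None = None,
) -> FamilyAlignment:
    """Read one aligned FASTA file into a :class:`FamilyAlignment`."""
    path = Path(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        rows.append((rec.id, parse_genome_id(header, genome_token), str(rec.seq)))
    if not rows:
        raise ValueError(f"no records in {path}")
    lengths = {len(r[2]) for r in rows}
    if len(lengths) != 1:
        bad = [rid for rid, _, res in rows if len(res) != len(rows[0][2])]
        raise ValueError(
            f"{path}: records are not aligned (ragged lengths; e.g. {bad[:3]})"
        )
    return FamilyAlignment(family_id=family_id or path.stem, rows=rows)


def read_nucleotide_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Plain FASTA -> list of (sequence_id, sequence)."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_profile_tsv(profiles: list[HomogeneityProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for j, (h, mask) in enumerate(zip(p.h, p.column_mask)):
            rows.append(
                {
                    "family_id": p.family_id,
                    "column_index": j,
                    "h": "" if np.isnan(h) else f"{h:.10g}",
                    "mask": mask,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> list[HomogeneityProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str})
    profiles = []
    for fam, sub in df.groupby("family_id", sort=False):
        sub = sub.sort_values("column_index")
        h = pd.to_numeric(sub["h"], errors="coerce").to_numpy(dtype=float)
        mask = list(sub["mask"])
        h[[m != SCORED for m in mask]] = np.nan
        profiles.append(HomogeneityProfile(family_id=fam, h=h, column_mask=mask))
    return profiles


def write_variability_tsv(
    records: list[VariabilityRecord],
    ctx: CladeContext,
    path: str | Path,
    extra: dict[str, dict] | None = None,
) -> None:
    """Per-family table; ``extra`` may add columns (n_seqs, paralogy, ...)."""
    rows = []
    for r in records:
        row = {
            "family_id": r.family_id,
            "h_C": r.h_C,
            "h_T": ctx.h_T,
            "v_C": r.v_C,
            "class": r.var_class,
            "f_conserved": r.position_fractions[0],
            "f_intermediate": r.position_fractions[1],
            "f_variable": r.position_fractions[2],
        }
        if extra and r.family_id in extra:
            row.update(extra[r.family_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_tsv(dist: np.ndarray, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(dist, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="family_id"
    )


def read_distance_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))


def write_embedding_tsv(emb: EmbeddingResult, path: str | Path) -> None:
    ids = emb.ids or [str(i) for i in range(emb.coordinates.shape[0])]
    cols = {
        f"dim{d + 1}": emb.coordinates[:, d] for d in range(emb.coordinates.shape[1])
    }
    pd.DataFrame({"family_id": ids, **cols}).to_csv(path, sep="\t", index=False)


def write_membership_tsv(partition, path: str | Path) -> None:
    """csCOG membership: cscog_id, sequence_id, genome_id."""
    rows = []
    for i, group in enumerate(partition.cscogs):
        for seq_id, genome_id in sorted(group):
            rows.append(
                {"cscog_id": f"cscog{i:04d}", "sequence_id": seq_id, "genome_id": genome_id}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gainloss_tsv(summaries, path: str | Path) -> None:
    rows = [
        {
            "family_id": s.family_id,
            "gains": s.n_gain_events,
            "losses": s.n_loss_events,
            "gain_total": s.gain_total,
            "loss_total": s.loss_total,
            "gain_total_no_root": s.gain_total_no_root,
            "ancestrality": s.ancestrality_class,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_msr_bed(annotations: list[MsrAnnotation], path: str | Path) -> None:
    """Merged MSR intervals, BED-like (0-based half-open)."""
    with open(path, "w") as fh:
        for ann in annotations:
            for iv in ann.intervals:
                fh.write(
                    f"{ann.sequence_id}\t{iv.start}\t{iv.end}\t{iv.motif}\t{iv.k}\n"
                )


def read_msr_bed(path: str | Path) -> list[tuple[str, int, int, str, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        seq_id, start, end, motif, k = line.split("\t")
        out.append((seq_id, int(start), int(end), motif, int(k)))
    return out


def write_msr_fraction_tsv(annotations: list[MsrAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sequence_id": a.sequence_id, "length": a.length, "msr_fraction": a.msr_fraction}
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)
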