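"""Readers and writers for the delimited-text formats used across the package.

Everything is plain TSV (or FASTA via Biopython, YAML for the pipeline
config):

* intensity profiles: columns (position, intensity);
* band tables / annotated ladders: columns (position, intensity,
  assigned_writhe, is_major);
* 2D spot tables: (dimension1_position, dimension2_position, intensity,
  true_writhe);
* differential-expression tables: (gene_id, log2FoldChange, padj,
  baseMean), with a case-insensitive alias map so externally produced
  tables load unchanged;
* counts matrices (genes x samples) with a sample->strain design file;
* motif hits as BED-like TSV with 1-based inclusive coordinates;
* growth curves (time_h, density[, strain]) and CFU series
  (generations, cfu_selective, cfu_nonselective).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .bands import Band, BandLadder
from .growth import GrowthCurve, RetentionSeries
from .motifs import MotifHit

__all__ = [
    "read_profile",
    "write_profile",
    "read_ladder",
    "write_ladder",
    "write_spots",
    "read_de_table",
    "read_counts",
    "read_design",
    "read_fasta",
    "write_motif_hits",
    "read_growth_curve",
    "read_retention_series",
    "load_sigma_config",
]

# accepted (lower-cased) column aliases for externally produced DE tables
DE_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "gene", "geneid", "id", "gene_name"),
    "log2FoldChange": ("log2foldchange", "log2fc", "lfc", "logfc"),
    "padj": ("padj", "p_adj", "adj_pval", "adjp", "fdr", "qvalue", "q_value"),
    "baseMean": ("basemean", "base_mean", "mean_expression", "avgexpr", "meanexpr"),
}


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"position", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns position, intensity")
    return df[["position", "intensity"]]


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def write_ladder(ladder: BandLadder, path: str | Path) -> None:
    ladder.to_frame().to_csv(path, sep="\t", index=False)


def read_ladder(path: str | Path) -> BandLadder:
    """Annotated ladder TSV -> BandLadder.

    Requires (position, intensity); optional assigned_writhe.  A band with
    assigned writhe 0 becomes the reference if present.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"position", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns position, intensity")
    df = df.sort_values("position")
    writhes = (
        df["assigned_writhe"] if "assigned_writhe" in df.columns else [None] * len(df)
    )
    bands = tuple(
        Band(
            position=float(p),
            intensity=float(i),
            assigned_writhe=None if pd.isna(w) else int(w),
        )
        for p, i, w in zip(df["position"], df["intensity"], writhes)
    )
    ref = next(
        (i for i, b in enumerate(bands) if b.assigned_writhe == 0),
        None,
    )
    return BandLadder(bands=bands, reference_index=ref)


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """DE statistics TSV with tolerant, case-insensitive column naming."""
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for canonical, aliases in DE_ALIASES.items():
        found = next((lower[a] for a in aliases if a in lower), None)
        if found is None:
            if canonical == "baseMean":
                continue  # optional
            raise ValueError(f"{path}: no column for {canonical} (aliases: {aliases})")
        rename[found] = canonical
    out = df.rename(columns=rename)
    out["gene_id"] = out["gene_id"].astype(str)
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count matrix, first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_design(path: str | Path) -> pd.Series:
    """Two-column (sample, strain) TSV -> sample->strain mapping."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"sample", "strain"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample, strain")
    return pd.Series(df["strain"].to_numpy(), index=df["sample"], name="strain")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_motif_hits(
    hits: list[MotifHit],
    sequence_name: str,
    window_length: int,
    path: str | Path,
) -> None:
    """BED-like TSV, 1-based inclusive start/end (subtract 1 from start for BED)."""
    rows = [
        {
            "sequence": sequence_name,
            "start": h.position,
            "end": h.position + window_length - 1,
            "strand": h.strand,
            "mismatches": h.mismatches,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["sequence", "start", "end", "strand", "mismatches"]
    ).to_csv(path, sep="\t", index=False)


def read_growth_curve(path: str | Path) -> GrowthCurve:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = next((c for c in ("time_h", "time", "t") if c in df.columns), None)
    ycol = next(
        (c for c in ("density", "cells_per_ml", "y") if c in df.columns), None
    )
    if tcol is None or ycol is None:
        raise ValueError(f"{path}: expected time and density columns")
    strain = str(df["strain"].iloc[0]) if "strain" in df.columns else ""
    return GrowthCurve(
        times_h=tuple(float(v) for v in df[tcol]),
        densities=tuple(float(v) for v in df[ycol]),
        strain=strain,
    )


def read_retention_series(path: str | Path) -> RetentionSeries:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    need = {"generations", "cfu_selective", "cfu_nonselective"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return RetentionSeries(
        generations=tuple(float(v) for v in df["generations"]),
        cfu_selective=tuple(int(v) for v in df["cfu_selective"]),
        cfu_nonselective=tuple(int(v) for v in df["cfu_nonselective"]),
    )


def load_sigma_config(path: str | Path) -> dict:
    """YAML config for the two-gel pipeline.

    Schema (keys at top level):
      plasmid: {name, length_bp, helical_repeat}
      growth_temp_C, gel_temp_C: numbers
      chloroquine_ug_ml: first-dimension concentration of the counting gel
      ladder_with_chl: path to annotated ladder TSV (required)
      ladder_no_chl: path (optional if delta_wr_chl given)
      delta_wr_chl: number (optional; transferred from a control sample)
      temp_coefficient, round_corrections: optional correction overrides
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    required = {"plasmid", "growth_temp_C", "gel_temp_C", "chloroquine_ug_ml",
                "ladder_with_chl"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"{path}: missing config keys {sorted(missing)}")
    if "ladder_no_chl" not in cfg and "delta_wr_chl" not in cfg:
        raise ValueError(f"{path}: need ladder_no_chl or delta_wr_chl")
    return cfg
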