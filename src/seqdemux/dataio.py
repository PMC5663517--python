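"""Input/output: site tables, genome windows, labeled datasets, result files.

Two input routes are supported:

* a TSV site table (columns: chrom, start[, end], labels) plus an indexed
  genome FASTA — fixed windows are extracted around each site midpoint
  (BED-style 0-based half-open coordinates);
* pre-extracted sequences in FASTA, with labels after a ``|`` in the header
  (semicolon-separated) or in a sidecar TSV (id<TAB>labels).

Outputs: per-label / per-subclass k-mer weight TSVs, motifs in MEME minimal
format, the motif x model score table, hills in BED, and a YAML run log.
Score heat-maps use a fixed color saturation of +/-0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import KmerSpace
from .hills import Hill
from .model import LabelStructure, WeightSet, instance_weights
from .motifs import PWM, MotifScoreTable

log = logging.getLogger(__name__)

SCORE_SATURATION = 0.4  # shared heat-map color scale: scores clamp to +/-0.4
MAX_N_FRACTION = 0.10


@dataclass
class GenomicSite:
    """A labeled point locus (0-based midpoint coordinate)."""

    chrom: str
    position: int
    labels: set[str]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if not self.labels:
            raise ValueError("site must carry at least one label")


@dataclass
class LabeledDataset:
    """Fixed-width sequences with per-sequence label sets and derived structure."""

    sequences: list[str]
    label_sets: list[set[str]]
    structure: LabelStructure = None
    Y: np.ndarray = None
    b: np.ndarray = None
    sites: list[GenomicSite] | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.label_sets):
            raise ValueError("sequences and label_sets length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences must all have the same length, got {lengths}")
        if self.structure is None:
            self.structure = LabelStructure.from_label_sets(self.label_sets)
        if self.Y is None:
            self.Y = self.structure.membership(self.label_sets)
        if self.b is None:
            self.b = instance_weights(self.label_sets, self.structure)

    @property
    def M(self) -> int:
        return len(self.sequences)


def _parse_labels(text: str, lineno: int) -> set[str]:
    labels = {t.strip() for t in text.split(";") if t.strip()}
    if not labels:
        raise ValueError(f"empty label field at line {lineno}")
    return labels


def read_site_table(path: str | Path) -> list[GenomicSite]:
    """Parse a TSV of chrom, start[, end], labels (semicolon-separated).

    With both start and end present the site is the interval midpoint;
    with a single coordinate it is taken as a point.
    """
    sites: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = parts[0]
            if len(parts) >= 4 and parts[2].lstrip("-").isdigit():
                start, end = int(parts[1]), int(parts[2])
                pos = (start + end) // 2
                label_text = parts[3]
            else:
                pos = int(parts[1])
                label_text = parts[2]
            sites.append(GenomicSite(chrom, pos, _parse_labels(label_text, lineno)))
    if not sites:
        raise ValueError(f"no sites parsed from {path}")
    return sites


def load_sites(path: str | Path, genome: str | Path, window: int = 150) -> LabeledDataset:
    """Extract fixed windows around site midpoints from an indexed genome.

    Each site expands to [position - window/2, position + window/2).
    Sites whose window leaves chromosome bounds or contains more than 10% N
    are dropped (count logged).
    """
    from pyfaidx import Fasta

    if window % 2:
        raise ValueError("window must be even")
    sites = read_site_table(path)
    fa = Fasta(str(genome))
    half = window // 2
    seqs, labels, kept_sites = [], [], []
    dropped = 0
    for site in sites:
        if site.chrom not in fa:
            raise KeyError(f"chromosome {site.chrom!r} not present in {genome}")
        chrom_len = len(fa[site.chrom])
        lo, hi = site.position - half, site.position + half
        if lo < 0 or hi > chrom_len:
            dropped += 1
            continue
        seq = str(fa[site.chrom][lo:hi]).upper()
        if seq.count("N") > MAX_N_FRACTION * window:
            dropped += 1
            continue
        seqs.append(seq)
        labels.append(site.labels)
        kept_sites.append(site)
    if dropped:
        log.info("dropped %d/%d sites (out of bounds or >10%% N)", dropped, len(sites))
    return LabeledDataset(sequences=seqs, label_sets=labels, sites=kept_sites)


def load_fasta(path: str | Path, label_table: str | Path | None = None) -> LabeledDataset:
    """Load pre-extracted sequences; labels from headers (``>id|A;B``) or sidecar TSV."""
    from Bio import SeqIO

    sidecar: dict[str, set[str]] = {}
    if label_table is not None:
        for lineno, line in enumerate(open(label_table), 1):
            if not line.strip():
                continue
            sid, lab = line.rstrip("\n").split("\t")[:2]
            sidecar[sid] = _parse_labels(lab, lineno)
    seqs, labels = [], []
    for lineno, rec in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        seqs.append(str(rec.seq).upper())
        if sidecar:
            if rec.id not in sidecar:
                raise KeyError(f"sequence {rec.id!r} missing from label table")
            labels.append(sidecar[rec.id])
        else:
            header = rec.description
            if "|" not in header:
                raise ValueError(f"record {rec.id!r}: no '|' label separator in header")
            labels.append(_parse_labels(header.split("|", 1)[1], lineno))
    return LabeledDataset(sequences=seqs, label_sets=labels)


def write_fasta(seqs: list[str], label_sets: list[set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (s, labs) in enumerate(zip(seqs, label_sets)):
            fh.write(f">seq{i}|{';'.join(sorted(labs))}\n{s}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs: list[PWM], path: str | Path,
               background: np.ndarray | None = None) -> None:
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.name or m.consensus}\n")
            # the E field carries the ZOOPS log-likelihood ratio so motif
            # strength survives a write/read round trip
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 20 E= {m.llr:.4g}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    motifs: list[PWM] = []
    name, rows, llr = None, [], 0.0
    in_matrix = False
    for line in open(path):
        s = line.strip()
        if s.startswith("MOTIF"):
            if name is not None and rows:
                motifs.append(PWM(np.array(rows), name=name, llr=llr))
            name, rows, llr, in_matrix = s.split()[1], [], 0.0, False
        elif s.startswith("letter-probability matrix"):
            in_matrix = True
            if "E=" in s:
                try:
                    llr = float(s.split("E=")[1].split()[0])
                except ValueError:
                    llr = 0.0
        elif in_matrix and s and s[0] in "0123456789.":
            rows.append([float(v) for v in s.split()[:4]])
        elif in_matrix and not s:
            in_matrix = False
    if name is not None and rows:
        motifs.append(PWM(np.array(rows), name=name, llr=llr))
    return motifs


# ---------------------------------------------------------------------------
# Result tables


def write_weight_tables(model: WeightSet, space: KmerSpace, outdir: str | Path) -> None:
    """Per-label and per-subclass k-mer weight TSVs (one row per canonical k-mer)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.W_lab.T, index=space.kmers,
                 columns=model.structure.labels).to_csv(
        outdir / "label_weights.tsv", sep="\t", float_format="%.12g")
    pd.DataFrame(model.W_sub[:, :-1].T, index=space.kmers,
                 columns=model.structure.subclass_names).to_csv(
        outdir / "subclass_weights.tsv", sep="\t", float_format="%.12g")


def read_weight_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def saturate(scores: np.ndarray, limit: float = SCORE_SATURATION) -> np.ndarray:
    """Clamp scores to the shared heat-map color range [-limit, +limit]."""
    return np.clip(scores, -limit, limit)


def write_score_table(table: MotifScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def plot_score_heatmap(table: MotifScoreTable, path: str | Path,
                       limit: float = SCORE_SATURATION) -> None:
    """Motif x model heat-map with the fixed +/-0.4 color saturation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.to_frame()
    fig, ax = plt.subplots(figsize=(1 + 0.6 * df.shape[1], 1 + 0.4 * df.shape[0]))
    im = ax.imshow(saturate(df.values, limit), cmap="RdBu_r",
                   vmin=-limit, vmax=limit, aspect="auto")
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(df.shape[0]), df.index)
    fig.colorbar(im, ax=ax, label="model score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_hills_bed(hills: list[Hill], path: str | Path,
                    sites: list[GenomicSite] | None = None,
                    window: int = 150) -> None:
    """Hills in BED format; genome-relative when the originating sites are known."""
    with open(path, "w") as fh:
        for h in hills:
            if sites is not None:
                site = sites[h.seq_id]
                offset = site.position - window // 2
                fh.write(f"{site.chrom}\t{offset + h.start}\t{offset + h.end}"
                         f"\t{h.source_model}\t{h.score:.4f}\n")
            else:
                fh.write(f"seq{h.seq_id}\t{h.start}\t{h.end}"
                         f"\t{h.source_model}\t{h.score:.4f}\n")


def write_outputs(model: WeightSet, space: KmerSpace,
                  motif_table: MotifScoreTable | None, outdir: str | Path,
                  hills: list[Hill] | None = None,
                  sites: list[GenomicSite] | None = None,
                  window: int = 150, config: dict | None = None) -> Path:
    """Write the full result bundle into ``outdir`` (created if needed)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_weight_tables(model, space, outdir)
    if motif_table is not None:
        write_meme(motif_table.motifs, outdir / "motifs.meme")
        write_score_table(motif_table, outdir / "motif_scores.tsv")
        plot_score_heatmap(motif_table, outdir / "motif_scores.png")
    else:
        write_meme([], outdir / "motifs.meme")
    if hills is not None:
        write_hills_bed(hills, outdir / "hills.bed", sites=sites, window=window)
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump({"config": config or {},
                        "labels": model.structure.labels,
                        "subclasses": model.structure.subclass_names}, fh)
    return outdir
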