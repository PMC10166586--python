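"""FASTA/TSV ingestion and the end-to-end pipeline driver.

The pipeline runs decompose -> encode -> align -> rearrange -> render and
writes six text artifacts into the output directory:

    decomposition.tsv   one row per segment
    motif_mapping.tsv   symbol / motif / count table
    aligned.fasta       gap-padded encoded alleles
    row_order.txt       display order, one allele id per line
    figure.svg|png|pdf  the motif-composition plot
    motif_table.tsv     symbol / motif / count / color legend

Every stage is also callable standalone through the library (or the CLI
subcommands), with these files as the interchange formats.  All outputs are
deterministic for a fixed configuration.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import (
    align,
    build_score_matrix,
    write_alignment_fasta,
)
from .decompose import (
    ScoringParams,
    decompose_all,
    write_decomposition_tsv,
)
from .encode import build_mapping, encode_allele, write_mapping
from .rearrange import rearrange, write_order
from .render import RenderSpec, render_plot, write_motif_table

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_alleles",
    "read_annotations",
    "run_pipeline",
]

logger = logging.getLogger("trtile")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def read_alleles(path) -> list[tuple[str, str]]:
    """Read TR alleles from a (multi-record, possibly wrapped) FASTA file.

    Returns (id, sequence) pairs in file order, sequences upper-cased.
    Duplicate ids, empty records and non-FASTA content are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, seq))
    return out


def read_annotations(path) -> dict[str, str]:
    """Read a sample-annotation TSV with required header ``sample\tgroup``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["sample", "group"]:
            raise ValueError(
                f"{path}: expected a header line 'sample\\tgroup'"
            )
        out: dict[str, str] = {}
        for lineno, row in enumerate(reader, 2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[row[0]] = row[1]
    return out


def read_motif_file(path) -> list[str]:
    """One motif per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        motifs = [
            line.strip().upper()
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    fasta: str | Path
    motifs: list[str]
    scoring: ScoringParams = field(default_factory=ScoringParams)
    private_threshold: int | str = 1  # count, or "auto"
    sort: str = "clustering"  # clustering|motif_count|length|lexicographic|manual
    manual_order: list[str] | None = None
    annotations: str | Path | None = None
    outdir: str | Path = "."
    output_format: str = "svg"
    seed: int = 0  # reserved for downstream tooling; the pipeline itself
    # is deterministic

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif is required")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        logger.info("%s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    return wrap


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and return the paths of the six artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alleles = _stage("input")(read_alleles, cfg.fasta)
    annotations = (
        _stage("input")(read_annotations, cfg.annotations)
        if cfg.annotations
        else {}
    )

    decomps, motifset = _stage("decompose")(
        decompose_all, alleles, cfg.motifs, cfg.scoring
    )
    dec_path = outdir / "decomposition.tsv"
    write_decomposition_tsv(decomps, dec_path)

    mapping = _stage("encode")(build_mapping, decomps, cfg.private_threshold)
    map_path = outdir / "motif_mapping.tsv"
    write_mapping(mapping, map_path)
    encoded = [(d.allele_id, encode_allele(d, mapping)) for d in decomps]

    matrix = _stage("align")(build_score_matrix, mapping)
    alignment = _stage("align")(align, encoded, matrix)
    aln_path = outdir / "aligned.fasta"
    write_alignment_fasta(alignment, aln_path)

    order = _stage("rearrange")(
        rearrange, alignment, cfg.sort, cfg.manual_order
    )
    order_path = outdir / "row_order.txt"
    write_order(order, order_path)

    spec = RenderSpec.from_mapping(
        mapping,
        order=order,
        annotations=annotations,
        fmt=cfg.output_format,
    )
    fig_path = outdir / f"figure.{cfg.output_format.lower()}"
    _stage("render")(render_plot, alignment, order, spec, fig_path)
    table_path = outdir / "motif_table.tsv"
    write_motif_table(mapping, spec.colors, table_path)

    return {
        "decomposition": dec_path,
        "mapping": map_path,
        "alignment": aln_path,
        "order": order_path,
        "figure": fig_path,
        "motif_table": table_path,
    }
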