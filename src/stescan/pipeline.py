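"""End-to-end orchestration: genomes -> LURs -> scan -> reports -> null model.

The screening protocol is two-pass: the motif is first searched only in
each genome's large unassigned regions; any genome with at least one LUR
hit is then automatically re-screened over its entire circular sequence,
and every hit is labelled with its genomic context (inside which feature,
inside a LUR, or intergenic, with an antisense note where the hit strand
opposes the feature strand).

All outputs are plain TSV/FASTA/Newick; a JSON manifest records
parameters, seeds and SHA-256 checksums of every written file so any
stage can be re-run and verified bit-for-bit.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .genome_io import (
    GenomeRecord,
    LUR,
    extract_lurs,
    extract_region,
    interval_length,
    read_genome,
    read_override_table,
    write_lur_table,
)
from .null_model import NullModelConfig, mc_null_test
from .scan import (
    DEFAULT_QUERY,
    MotifHit,
    MotifQuery,
    ScoringScheme,
    scan_genome,
    scan_sequence,
)
from .similarity import upstream_flank

log = logging.getLogger("stescan")


@dataclass
class RunConfig:
    genome_paths: list[str]
    out_dir: str
    motif: str = DEFAULT_QUERY.sequence
    match_score: int = 5
    mismatch_score: int = -4
    Ts: int = 56
    min_lur_length: int = 100
    strand_mode: str = "both"
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    run_null_model: bool = True
    override_table: str | None = None
    tree_alignment: str | None = None
    n_boot: int = 1000

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ValueError(f"bad config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.genome_paths:
            raise ValueError("no genomes: config lists no input files")
        for p in self.genome_paths:
            if not Path(p).exists():
                raise ValueError(f"input file not found: {p}")
        if self.run_null_model and self.seed is None:
            raise ValueError("seed is mandatory when the null model stage is enabled")


def annotate_hits(genome: GenomeRecord, hits: Sequence[MotifHit], lurs: Sequence[LUR] | None = None) -> list[MotifHit]:
    """Label each hit with its genomic context.

    Context is ``in_feature:<name>`` (plus ``,antisense`` when strands
    oppose), else ``in_LUR``, else ``intergenic``. Feature overlap is
    judged at the hit midpoint so a hit dangling one base into a gene is
    still attributed to where its bulk lies.
    """
    n = len(genome)
    if lurs is None:
        try:
            lurs = extract_lurs(genome)
        except ValueError:
            lurs = []

    def contains(interval: tuple[int, int], pos: int) -> bool:
        s, e = interval
        return s <= pos < e if e > s else pos >= s or pos < e

    for hit in hits:
        mid = (hit.start + hit.W // 2) % n
        context = "intergenic"
        for feat in genome.features:
            if contains(feat.interval, mid):
                context = f"in_feature:{feat.name or feat.kind}"
                if feat.strand != hit.strand:
                    context += ",antisense"
                break
        else:
            for lur in lurs:
                if contains(lur.interval, mid):
                    context = "in_LUR"
                    break
        hit.context = context
    return list(hits)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_hits(hits: Sequence[MotifHit], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_id", "start", "end", "strand", "identities", "score", "pct", "context"])
        for h in hits:
            w.writerow([h.target_id, h.start + 1, h.start + h.W, h.strand, h.m, h.score, f"{h.pct:.1f}", h.context])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Stages: read genomes -> extract LURs -> scan LURs -> similarity and
    flank reports -> conditional genome-wide re-scan -> null-model table.
    Genomes without boundary features are skipped with a warning, not
    fatal. Outputs are deterministic for a fixed config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    motif = MotifQuery(config.motif)
    scheme = ScoringScheme(config.match_score, config.mismatch_score, config.Ts)
    overrides = read_override_table(config.override_table) if config.override_table else {}

    genomes: list[GenomeRecord] = []
    skipped: list[str] = []
    for path in config.genome_paths:
        try:
            g = read_genome(path)
        except ValueError as exc:
            raise RuntimeError(f"stage=read genome={path}: {exc}") from exc
        if overrides.get(g.id):
            g = read_genome(path, overrides=overrides[g.id])
        genomes.append(g)

    all_lurs: list[LUR] = []
    lur_by_genome: dict[str, list[LUR]] = {}
    for g in genomes:
        try:
            lurs = extract_lurs(g, min_length=config.min_lur_length)
        except ValueError as exc:
            log.warning("skipping %s: %s", g.id, exc)
            skipped.append(g.id)
            continue
        lur_by_genome[g.id] = lurs
        all_lurs.extend(lurs)
    write_lur_table(all_lurs, out / "lurs.tsv")

    lur_hits: list[MotifHit] = []
    flank_rows: list[dict] = []
    genomes_with_lur_hit: list[GenomeRecord] = []
    for g in genomes:
        if g.id in skipped:
            continue
        found = False
        for lur in lur_by_genome[g.id]:
            hits = scan_sequence(
                lur.sequence, motif, scheme, strand_mode=config.strand_mode,
                target_id=g.id,
            )
            for h in hits:
                # report on the genome axis
                h.start = (h.start + lur.interval[0]) % len(g)
                h.context = "in_LUR"
                rec = upstream_flank(g.sequence, h, circular=g.circular)
                flank_rows.append(
                    dict(hit_ref=rec.hit_ref, pct=f"{h.pct:.1f}", flank30=rec.flank30,
                         A_fraction=f"{rec.flank_A_fraction:.3f}",
                         longest_A_run=rec.flank_longest_A_run)
                )
            if hits:
                found = True
            lur_hits.extend(hits)
        if found:
            genomes_with_lur_hit.append(g)
    _write_hits(lur_hits, out / "lur_hits.tsv")
    with open(out / "flanks.tsv", "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["hit_ref", "pct", "flank30", "A_fraction", "longest_A_run"],
            delimiter="\t", lineterminator="\n",
        )
        w.writeheader()
        w.writerows(flank_rows)

    # two-pass rule: genome-wide re-screen of every genome with a LUR hit
    genome_hits: list[MotifHit] = []
    for g in genomes_with_lur_hit:
        genome_hits.extend(scan_genome(g, motif, scheme, strand_mode=config.strand_mode))
    _write_hits(genome_hits, out / "genome_hits.tsv")

    lur_only = sum(
        1
        for g in genomes_with_lur_hit
        if all(h.context.startswith("in_LUR") or h.context == "intergenic"
               for h in genome_hits if h.target_id == g.id)
    )

    null_rows: list[dict] = []
    if config.run_null_model:
        for gi, g in enumerate(genomes_with_lur_hit):
            for lur in lur_by_genome[g.id]:
                best = [h for h in lur_hits if h.target_id == g.id
                        and contains_in(lur.interval, h.start, len(g))]
                if not best:
                    continue
                k = max(h.m for h in best)
                for mode in ("empirical", "uniform"):
                    cfg = NullModelConfig(
                        L=lur.length, freqs=lur.freqs, k=k, motif=motif,
                        n_reps=config.n_reps,
                        seed=(config.seed or 0) + 1000 + gi,
                        freq_mode=mode,
                    )
                    res = mc_null_test(cfg)
                    null_rows.append(
                        dict(genome_id=g.id, L=lur.length, k=k, mode=mode,
                             total_hits=res.total_hits,
                             seqs_with_hit=res.seqs_with_hit,
                             pseudo_p=f"{res.pseudo_p:.3f}",
                             expected_total=f"{res.analytic_expected_total:.3f}",
                             significant=res.pseudo_p <= config.alpha)
                    )
        with open(out / "null_model.tsv", "w", newline="") as fh:
            w = csv.DictWriter(
                fh,
                fieldnames=["genome_id", "L", "k", "mode", "total_hits",
                            "seqs_with_hit", "pseudo_p", "expected_total", "significant"],
                delimiter="\t", lineterminator="\n",
            )
            w.writeheader()
            w.writerows(null_rows)

    if config.tree_alignment:
        from .phylogeny import bootstrap_support, read_alignment_fasta, write_newick

        aln = read_alignment_fasta(config.tree_alignment)
        tree = bootstrap_support(aln, n_boot=config.n_boot, seed=config.seed or 0)
        write_newick(tree, out / "tree.nwk")

    manifest = {
        "stescan_version": __version__,
        "parameters": {
            "motif": motif.sequence, "Ts": scheme.Ts,
            "match": scheme.match_score, "mismatch": scheme.mismatch_score,
            "min_lur_length": config.min_lur_length,
            "strand_mode": config.strand_mode,
            "n_reps": config.n_reps, "seed": config.seed, "alpha": config.alpha,
        },
        "n_genomes": len(genomes),
        "skipped_genomes": skipped,
        "n_lurs": len(all_lurs),
        "n_lur_hits": len(lur_hits),
        "genomes_rescanned": [g.id for g in genomes_with_lur_hit],
        "n_genome_hits": len(genome_hits),
        "lur_only_genomes": lur_only,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def contains_in(interval: tuple[int, int], pos: int, n: int) -> bool:
    """Membership of a position in a possibly wrapped interval."""
    s, e = interval
    return s <= pos < e if e > s else pos >= s or pos < e
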