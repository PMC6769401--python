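"""The integrated single-run pipeline.

Orchestrates: input reading -> Mock generation -> three proteome scans
(Test, Control, Mock) -> peptide clustering and mapping statistics ->
signal profiles -> background/Control subtraction -> m-/z-scoring and
outlier selection -> gene-list extraction -> over-representation analysis
with bootstrap reranking -> systemic processes, gene prioritization and
the gene x process heatmap.  Every output is written to ``outdir`` together
with a manifest recording parameters, seeds and input checksums.

The run is a pure function of (inputs, configuration, seed): rerunning
with identical inputs reproduces every output byte for byte (manifest
timestamp aside).  The Mock generator consumes the run seed directly and
the bootstrap its own stream of the same seed, so composing the satellite subcommands
manually reproduces the integrated run.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import enrichment as enr
from . import io_formats as io
from . import mapping
from . import profiles_scoring as ps
from . import repertoire_tools as rt

logger = logging.getLogger(__name__)

#: Below this number of unique Test peptides the mapping density is too low
#: for a stable m-score distribution on a full proteome.
RECOMMENDED_MIN_UNIQUE = 40000


@dataclass
class RunConfig:
    test_path: str | Path
    proteome_path: str | Path
    aaf_path: str | Path
    gmt_path: Optional[str | Path] = None
    obo_path: Optional[str | Path] = None
    control_path: Optional[str | Path] = None
    no_control: bool = False
    test_format: str = "list"
    control_format: str = "list"
    h: float = 0.6
    z_cut: float = 2.58
    p_cut: float = 0.05
    corrected_cut: float = 0.05
    B: int = 1000
    seed: int = 0
    matrix_path: Optional[str | Path] = None
    outdir: str | Path = "pepmimic_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must lie in [0, 1], got {self.h}")
        if self.z_cut <= 0:
            raise ValueError(f"z_cut must be positive, got {self.z_cut}")


@dataclass
class RunResult:
    outdir: Path
    scores: dict[str, ps.ProteinScore]
    selected: list[ps.ProteinScore]
    genes: list[str]
    enrichment: list[enr.EnrichmentResult] = field(default_factory=list)
    processes: list[enr.SystemicProcess] = field(default_factory=list)
    priorities: list[enr.GenePriority] = field(default_factory=list)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("pepmimic").addHandler(handler)
    try:
        return _run_pipeline(cfg, outdir)
    finally:
        logging.getLogger("pepmimic").removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: RunConfig, outdir: Path) -> RunResult:
    matrix = (
        mapping.read_matrix(cfg.matrix_path) if cfg.matrix_path else mapping.PAM30
    )

    # ---- inputs ------------------------------------------------------
    test = io.read_repertoire(cfg.test_path, format=cfg.test_format, label="T")
    if len(test) < RECOMMENDED_MIN_UNIQUE:
        logger.warning(
            "Test repertoire has %d unique peptides; at least %d are "
            "recommended for stable m-score distributions on a full proteome",
            len(test),
            RECOMMENDED_MIN_UNIQUE,
        )
    aaf = io.read_aaf(cfg.aaf_path)
    proteome = io.read_proteome(cfg.proteome_path)
    gene_symbols = {p.protein_id: p.gene_symbol for p in proteome}

    if cfg.no_control:
        control = None
    elif cfg.control_path is not None:
        control = io.read_repertoire(
            cfg.control_path, format=cfg.control_format, label="C"
        )
        if len(control) != len(test):
            logger.warning(
                "Control size (%d) differs from Test size (%d); consider "
                "balancing with unique Test sequences", len(control), len(test)
            )
    else:
        control = rt.make_placeholder_control(test.length)
        logger.info("no Control supplied: using single poly-W placeholder")

    # ---- mock + scans ------------------------------------------------
    mock = rt.generate_mock(test, aaf, seed=cfg.seed)
    hits_t = mapping.scan_proteome(test, proteome, cfg.h, matrix)
    hits_m = mapping.scan_proteome(mock, proteome, cfg.h, matrix)
    hits_c = (
        mapping.scan_proteome(control, proteome, cfg.h, matrix)
        if control is not None
        else []
    )

    mapping.cluster_peptides(test, cfg.h, matrix)
    mapping.annotate_mapping_stats(test, hits_t)
    mapping.cluster_peptides(mock, cfg.h, matrix)
    mapping.annotate_mapping_stats(mock, hits_m)

    io.write_hits(hits_t, test, outdir / "hits_test.tsv")
    io.write_hits(hits_m, mock, outdir / "hits_mock.tsv")

    # ---- profiles ----------------------------------------------------
    prof_t = ps.build_profile(hits_t, proteome)
    prof_m = ps.build_profile(hits_m, proteome)
    prof_c = ps.build_profile(hits_c, proteome) if control is not None else None
    prof_tm = ps.subtract_profiles(prof_t, prof_m)
    prof_final = (
        ps.subtract_profiles(prof_t, prof_m, prof_c)
        if prof_c is not None
        else prof_tm
    )

    io.write_profiles(prof_t, outdir / "profiles_test.tsv")
    io.write_profiles(prof_m, outdir / "profiles_mock.tsv")
    if prof_c is not None:
        io.write_profiles(prof_c, outdir / "profiles_control.tsv")
    io.write_profiles(prof_tm, outdir / "profiles_test_minus_mock.tsv")
    io.write_profiles(prof_final, outdir / "profiles_final.tsv")

    # ---- scoring -----------------------------------------------------
    mscores = {pid: ps.m_score(vec) for pid, vec in prof_final.items()}
    try:
        scores = ps.z_scores(mscores)
    except ValueError as exc:
        logger.warning("scoring degenerate (%s); no outliers selected", exc)
        scores = {
            pid: ps.ProteinScore(pid, m_score=m, z_score=float("-inf"))
            for pid, m in mscores.items()
        }
        selected = []
    else:
        selected = ps.select_outliers(scores, cfg.z_cut)
    io.write_scores(scores, gene_symbols, outdir / "scores.tsv")

    genes: list[str] = []
    for s in selected:  # m-score order; isoforms collapse to one symbol
        sym = gene_symbols[s.protein_id]
        if sym not in genes:
            genes.append(sym)
    (outdir / "genes.txt").write_text("".join(f"{g}\n" for g in genes))

    result = RunResult(
        outdir=outdir, scores=scores, selected=selected, genes=genes
    )

    # ---- enrichment --------------------------------------------------
    if not selected:
        logger.warning("empty outlier set: enrichment skipped")
    elif cfg.gmt_path is None:
        logger.info("no annotation file supplied: enrichment skipped")
    else:
        terms = io.read_gmt(cfg.gmt_path)
        dag = io.read_obo(cfg.obo_path) if cfg.obo_path else None
        ann = enr.AnnotationSet(terms=terms, dag=dag)
        if dag is not None:
            ann = enr.propagate_annotations(ann)
        results = enr.enrich_terms(genes, ann)
        n_query = results[0].n
        results = enr.bootstrap_prioritize(
            results, ann, n_query=n_query, B=cfg.B, seed=cfg.seed,
            p_cut=cfg.p_cut, corrected_cut=cfg.corrected_cut,
        )
        write_enrichment(results, outdir / "enriched_terms.tsv")
        significant = [r for r in results if r.significant]
        processes = enr.cluster_terms_to_processes(significant, ann, genes)
        priorities = enr.prioritize_genes(processes, genes)
        write_gene_ranking(priorities, outdir / "gene_ranking.tsv")
        if priorities:
            matrix_df = enr.gene_process_matrix(processes, priorities)
            matrix_df.to_csv(outdir / "gene_process_matrix.tsv", sep="\t")
            enr.plot_gene_process_heatmap(
                matrix_df, outdir / "gene_process_heatmap.png"
            )
        else:
            logger.warning("no significant process: gene ranking is empty")
        result.enrichment = results
        result.processes = processes
        result.priorities = priorities

    _write_manifest(cfg, outdir)
    return result


def write_enrichment(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tname\tk\tK\tn\tN\tp_hyper\tboot_score\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_hyper:.6g}\t{r.boot_score:.6g}\t{int(r.significant)}\n"
            )


def write_gene_ranking(priorities, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_symbol\tprocess_count\n")
        for p in priorities:
            fh.write(f"{p.rank}\t{p.gene_symbol}\t{p.process_count}\n")


def _write_manifest(cfg: RunConfig, outdir: Path) -> None:
    lines = [f"pepmimic_version\t{__version__}"]
    lines.append(f"timestamp\t{time.strftime('%Y-%m-%dT%H:%M:%S')}")
    for name in (
        "h", "z_cut", "p_cut", "corrected_cut", "B", "seed", "no_control",
        "test_format", "control_format",
    ):
        lines.append(f"param_{name}\t{getattr(cfg, name)}")
    for name in ("test_path", "control_path", "aaf_path", "proteome_path",
                 "gmt_path", "obo_path", "matrix_path"):
        p = getattr(cfg, name)
        if p is not None:
            lines.append(f"input_{name}\t{p}")
            lines.append(f"sha256_{name}\t{_sha256(p)}")
    (outdir / "run_manifest.txt").write_text("".join(f"{ln}\n" for ln in lines))
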