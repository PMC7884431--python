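"""End-to-end workflow orchestration with config validation and reports.

The workflow mirrors the positional-cloning-plus-capture strategy: a
nuclear side (ORF screen -> PPR annotation -> orthogroup clustering ->
restorer-candidate selection) and a mitochondrial side (ORF screen ->
genome comparison / chimera annotation -> binding-site prediction ->
coverage normalisation and cleavage-site localisation).  Execution is
single-process and deterministic: the same config and seed produce
byte-identical report tables.

Configs are TOML (or equivalent dicts) with a ``[simulate]`` block to
generate the synthetic input bundle, or explicit input paths per stage.
Unknown keys are rejected at validation time.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .formats import (
    ParameterError,
    SeqRecord,
    parse_bedgraph,
    parse_fasta,
    write_bedgraph,
    write_fasta,
)
from .mito_compare import UniqueRegionParams, annotate_chimera, species_specific_orfs, unique_regions
from .orf_scan import OrfParams, find_orfs
from .orthocluster import ClusteringParams, greedy_cluster
from .ppr_annotate import annotate_protein, default_models, extract_code_pairs
from .ppr_code import default_code_table, scan_transcript, site_cleavage_offset
from .rf_select import read_panel, select_candidates
from .rnaseq_mito import CleavageParams, detect_cleavage, normalize_coverage
from .synthetic_data import (
    default_panel,
    simulate_chimeric_genomes,
    simulate_coverage,
    simulate_counts,
    simulate_rfl_panel,
)

_TOP_KEYS = {"seed", "outdir", "simulate", "nuclear", "mito"}
_SIM_KEYS = {"enabled", "n_families", "cleavage_positions", "base_len"}
_NUC_KEYS = {"enabled", "proteins_fasta", "panel_tsv", "mode", "min_p",
             "full_length_min_aa", "identity_c"}
_MITO_KEYS = {"enabled", "genome_a", "genome_b", "donor_cds", "min_codons",
              "fertile_bedgraph", "sterile_bedgraph", "window_w", "min_fold",
              "search_start", "search_end"}


def validate_config(config: dict) -> dict:
    """Check keys and fill defaults; raises ParameterError on problems."""
    if not isinstance(config, dict):
        raise ParameterError("config must be a mapping")
    missing = [k for k in ("outdir",) if k not in config]
    unknown = sorted(set(config) - _TOP_KEYS)
    problems = []
    if missing:
        problems.append(f"missing keys: {missing}")
    if unknown:
        problems.append(f"unknown keys: {unknown}")
    for block, allowed in (("simulate", _SIM_KEYS), ("nuclear", _NUC_KEYS),
                           ("mito", _MITO_KEYS)):
        extra = sorted(set(config.get(block, {})) - allowed)
        if extra:
            problems.append(f"unknown keys in [{block}]: {extra}")
    if problems:
        raise ParameterError("invalid config: " + "; ".join(problems))
    out = {
        "seed": int(config.get("seed", 1)),
        "outdir": str(config["outdir"]),
        "simulate": dict(config.get("simulate", {"enabled": False})),
        "nuclear": dict(config.get("nuclear", {"enabled": True})),
        "mito": dict(config.get("mito", {"enabled": True})),
    }
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_bundle(outdir: Path, seed: int, n_families: int = 5,
                    cleavage_positions=None, base_len: int = 40_000) -> dict:
    """Generate the full synthetic input bundle on disk.

    Writes RFL dna/protein FASTAs, a panel TSV, a mitochondrial genome
    pair plus donor CDS, fertile/sterile coverage bedGraphs per restored
    genotype, and a truth.json sidecar.  Returns the path map.
    """
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    genes, panel, panel_truth = simulate_rfl_panel(
        n_families=n_families, seed=seed)
    write_fasta([SeqRecord(id=g.id, sequence=g.dna, alphabet="dna")
                 for g in genes], inputs / "rfl_dna.fasta")
    write_fasta([SeqRecord(id=g.id, sequence=g.protein, alphabet="protein")
                 for g in genes], inputs / "rfl_protein.fasta")
    rows = []
    for g in panel.genotypes:
        ph = panel.phenotype[g]
        rows.append([g, int(ph.carries_Rf1), int(ph.carries_Rf3),
                     int(ph.maintainer), int(ph.is_timopheevii)])
    _write_tsv(pd.DataFrame(rows, columns=["genotype", "carries_Rf1",
                                           "carries_Rf3", "maintainer",
                                           "is_timopheevii"]),
               inputs / "panel.tsv")

    genome_a, genome_b, donor, mito_truth = simulate_chimeric_genomes(
        base_len=base_len, seed=seed)
    write_fasta([genome_a], inputs / "mito_a.fasta")
    write_fasta([genome_b], inputs / "mito_b.fasta")
    write_fasta([donor], inputs / "donor_cds.fasta")

    u0, u1 = mito_truth.planted["unique_interval"]
    if cleavage_positions is None:
        cleavage_positions = {"Rf1": u0 + 150, "Rf3": u0 + 260}
    tracks, cov_truth = simulate_coverage(
        ref_len=len(genome_a.sequence), cleavage_pos=dict(cleavage_positions),
        seed=seed, ref_id=genome_a.id)
    paths = {}
    for genotype, (fert, ster) in tracks.items():
        fp = inputs / f"coverage_{genotype}_fertile.bedgraph"
        sp = inputs / f"coverage_{genotype}_sterile.bedgraph"
        write_bedgraph(fert, fp)
        write_bedgraph(ster, sp)
        paths[genotype] = (fp, sp)

    counts, counts_truth = simulate_counts(seed=seed)
    df = pd.DataFrame(counts.counts, index=counts.transcript_ids,
                      columns=counts.sample_ids)
    df.insert(0, "length", counts.lengths.astype(int))
    df.index.name = "transcript"
    df.to_csv(inputs / "counts.tsv", sep="\t", lineterminator="\n")

    truth = {
        "panel": panel_truth.planted,
        "mito": mito_truth.planted,
        "coverage": cov_truth.planted,
        "counts": counts_truth.planted,
    }
    with open(inputs / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return {
        "proteins_fasta": inputs / "rfl_protein.fasta",
        "panel_tsv": inputs / "panel.tsv",
        "genome_a": inputs / "mito_a.fasta",
        "genome_b": inputs / "mito_b.fasta",
        "donor_cds": inputs / "donor_cds.fasta",
        "coverage": paths,
        "truth": truth,
    }


def run_workflow(config: dict) -> Path:
    """Run the enabled stages; returns the report directory.

    Any stage error aborts with the stage named; partial outputs are
    retained.  Re-running with identical inputs overwrites identically.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"rflkit {__version__} seed={cfg['seed']}"]
    with open(outdir / "config.resolved.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    bundle = None
    if cfg["simulate"].get("enabled"):
        t0 = time.perf_counter()
        bundle = simulate_bundle(
            outdir, cfg["seed"],
            n_families=int(cfg["simulate"].get("n_families", 5)),
            base_len=int(cfg["simulate"].get("base_len", 40_000)),
        )
        log_lines.append(f"simulate: {time.perf_counter() - t0:.2f}s")

    candidate_protein = None
    nuc = cfg["nuclear"]
    if nuc.get("enabled", True):
        t0 = time.perf_counter()
        try:
            candidate_protein = _run_nuclear(nuc, bundle, outdir)
        except Exception as exc:
            _flush_log(outdir, log_lines + [f"nuclear: FAILED ({exc})"])
            raise ParameterError(f"stage 'nuclear' failed: {exc}") from exc
        log_lines.append(f"nuclear: {time.perf_counter() - t0:.2f}s")

    mito = cfg["mito"]
    if mito.get("enabled", True):
        t0 = time.perf_counter()
        try:
            _run_mito(mito, bundle, outdir, candidate_protein)
        except Exception as exc:
            _flush_log(outdir, log_lines + [f"mito: FAILED ({exc})"])
            raise ParameterError(f"stage 'mito' failed: {exc}") from exc
        log_lines.append(f"mito: {time.perf_counter() - t0:.2f}s")

    _flush_log(outdir, log_lines)
    return outdir


def _flush_log(outdir: Path, lines) -> None:
    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _resolve(block: dict, bundle, key: str):
    if key in block:
        return Path(block[key])
    if bundle and key in bundle:
        return bundle[key]
    raise ParameterError(f"no input for {key!r} (set it or enable simulate)")


def _run_nuclear(block: dict, bundle, outdir: Path) -> None:
    proteins = parse_fasta(_resolve(block, bundle, "proteins_fasta"),
                           alphabet="protein")
    panel = read_panel(_resolve(block, bundle, "panel_tsv"))
    mode = block.get("mode", "Rf1")
    models = default_models()
    genes = []
    arch_rows = []
    for rec in proteins:
        genotype = rec.id.split(".", 1)[0]
        gene = annotate_protein(
            rec.id, genotype, rec.sequence, models=models,
            rfl_min_p=int(block.get("min_p", 10)),
            full_length_min_aa=int(block.get("full_length_min_aa", 500)),
        )
        genes.append(gene)
        pairs = extract_code_pairs(gene.architecture, rec.sequence)
        arch_rows.append([gene.id, gene.genotype, gene.codons,
                          gene.architecture.p_count, gene.status,
                          ",".join(a + b for a, b in pairs)])
    _write_tsv(pd.DataFrame(arch_rows, columns=[
        "gene", "genotype", "codons", "p_count", "status", "code_pairs"]),
        outdir / "architectures.tsv")

    rfl = [g for g in genes if g.is_rfl or g.status == "partial"]
    groups = greedy_cluster(rfl, ClusteringParams(
        identity_c=float(block.get("identity_c", 0.96))))
    grp_rows = [
        [g.group_id, g.representative,
         ";".join(i for _, i, _ in g.members),
         ";".join(sorted(g.genotypes))]
        for g in groups
    ]
    _write_tsv(pd.DataFrame(grp_rows, columns=[
        "group_id", "representative", "members", "genotypes"]),
        outdir / "orthogroups.tsv")

    placements = {g.group_id: "in" for g in groups}
    seqs = {g.id: g.protein for g in genes}
    reports = select_candidates(groups, panel, placements, mode=mode,
                                sequences=seqs)
    rep_rows = [
        [r.group_id, *[int(r.rule_results[k]) for k in sorted(r.rule_results)],
         r.verdict, ";".join(r.reasons)]
        for r in reports
    ]
    cols = ["group_id", *sorted(reports[0].rule_results), "verdict", "reasons"] \
        if reports else ["group_id", "verdict", "reasons"]
    _write_tsv(pd.DataFrame(rep_rows, columns=cols), outdir / "candidates.tsv")

    # hand the first candidate group's longest full-length restorer member
    # to the mitochondrial side for binding-site prediction
    by_group = {g.group_id: g for g in groups}
    for r in reports:
        if r.verdict != "candidate":
            continue
        members = [gid for _, gid, st in by_group[r.group_id].members
                   if st == "full_length"]
        if members:
            return max((seqs[m] for m in members), key=len)
    return None


def _run_mito(block: dict, bundle, outdir: Path,
              candidate_protein: str | None = None) -> None:
    genome_a = parse_fasta(_resolve(block, bundle, "genome_a"))[0]
    genome_b = parse_fasta(_resolve(block, bundle, "genome_b"))[0]
    donors = parse_fasta(_resolve(block, bundle, "donor_cds"))
    min_codons = int(block.get("min_codons", 101))
    orfs = find_orfs(genome_a, OrfParams(min_nt=279,
                                         min_codons_filter=min_codons))
    specific = species_specific_orfs(orfs, genome_a, genome_b)
    regions = unique_regions(genome_a, genome_b, UniqueRegionParams())
    _write_tsv(pd.DataFrame(
        [[genome_a.id, s, e, e - s] for s, e in regions],
        columns=["ref", "start", "end", "length_nt"]),
        outdir / "unique_regions.tsv")

    chim_rows = []
    best = None
    for orf in specific:
        ann = annotate_chimera(orf, donors, genome_a, unique_intervals=regions)
        chim_rows.append([ann.orf_id, orf.start + 1, orf.end, orf.strand,
                          ann.orf_codons, ann.donor_gene or "",
                          ann.shared_prefix_codons, ann.unique_nt,
                          ann.unique_codons])
        if best is None or ann.shared_prefix_codons > best[0].shared_prefix_codons:
            best = (ann, orf)
    _write_tsv(pd.DataFrame(chim_rows, columns=[
        "orf", "start", "end", "strand", "codons", "donor",
        "shared_prefix_codons", "unique_nt", "unique_codons"]),
        outdir / "chimeras.tsv")

    # cleavage localisation per restored genotype
    calls = []
    cov = (bundle or {}).get("coverage", {})
    if "fertile_bedgraph" in block and "sterile_bedgraph" in block:
        cov = {"restored": (Path(block["fertile_bedgraph"]),
                            Path(block["sterile_bedgraph"]))}
    w = int(block.get("window_w", 50))
    search = None
    if best is not None:
        _, orf = best
        search = (max(0, orf.start - 300),
                  min(len(genome_a.sequence), orf.end + 300))
    if "search_start" in block and "search_end" in block:
        search = (int(block["search_start"]), int(block["search_end"]))
    for genotype, (fp, sp) in sorted(cov.items()):
        fert = normalize_coverage(parse_bedgraph(fp, len(genome_a.sequence)))
        ster = normalize_coverage(parse_bedgraph(sp, len(genome_a.sequence)))
        call = detect_cleavage(fert, ster, CleavageParams(
            window_w=w, min_fold=float(block.get("min_fold", 3.0)),
            search_region=search))
        calls.append([genotype, call.ref_id, call.strand, call.position + 1,
                      round(call.fold, 3), int(call.passed)])
    _write_tsv(pd.DataFrame(calls, columns=[
        "genotype", "ref", "strand", "position", "fold", "passed"]),
        outdir / "cleavage_calls.tsv")

    # binding sites of the candidate restorer on the chimera transcript
    site_rows = []
    if best is not None and candidate_protein:
        ann, orf = best
        from .formats import reverse_complement
        tx_seq = genome_a.sequence[orf.start:orf.end]
        if orf.strand == "-":
            tx_seq = reverse_complement(tx_seq)
        tx = SeqRecord(id=ann.orf_id, sequence=tx_seq, alphabet="dna")
        for site, offset, consistent in predict_sites_for_candidate(
                candidate_protein, tx, top_n=5):
            site_rows.append([tx.id, site.start + 1, site.end,
                              round(site.total, 3), site.rank])
    _write_tsv(pd.DataFrame(site_rows, columns=[
        "transcript", "start", "end", "total", "rank"]),
        outdir / "binding_sites.tsv")


def predict_sites_for_candidate(protein: str, transcript: SeqRecord,
                                top_n: int = 5, cleavage_pos: int | None = None):
    """Binding sites of a candidate restorer on a transcript.

    Convenience chain used by the CLI: annotate the protein, take its
    P-motif code pairs, scan the transcript, and (optionally) report the
    offset of each site to a cleavage position.
    """
    gene = annotate_protein("candidate", "NA", protein)
    pairs = extract_code_pairs(gene.architecture, protein)
    sites = scan_transcript(pairs, transcript, default_code_table(), top_n=top_n)
    out = []
    for s in sites:
        offset, consistent = (None, None)
        if cleavage_pos is not None:
            offset, consistent = site_cleavage_offset(s, cleavage_pos)
        out.append((s, offset, consistent))
    return out
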