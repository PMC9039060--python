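"""Pipeline orchestration: chains the analysis stages over a working
directory, each stage reading the files earlier stages wrote so that any
stage can be re-run independently.

Stage order: simulate -> ani -> snps -> ld -> popstruct -> genefam ->
mge -> crispr -> primers.  All tabular interchange is TSV; run summaries
are JSON.  Randomness per stage comes from an independent substream keyed
by (root seed, stage name).
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import crispr as crispr_mod
from . import genefam as genefam_mod
from . import ld as ld_mod
from . import mge as mge_mod
from . import popstructure as pop_mod
from . import primers as primers_mod
from . import snp as snp_mod
from .config import PipelineConfig
from .io import read_fasta, read_manifest, read_tsv, write_fasta, write_manifest, write_tsv
from .simulate import SagParams, simulate_community
from .types import AlignmentSegment, GenomeKind, SeqRecord

logger = logging.getLogger(__name__)

STAGES = ["simulate", "ani", "snps", "ld", "popstruct", "genefam", "mge", "crispr", "primers"]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _segments_frame(segments: list[AlignmentSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_genome": s.query_genome,
                "query_contig": s.query_contig,
                "qstart": s.query_start,
                "qend": s.query_end,
                "ref_contig": s.ref_contig,
                "rstart": s.ref_start,
                "rend": s.ref_end,
                "strand": s.strand,
            }
            for s in segments
        ]
    )


def _segments_from_frame(df: pd.DataFrame) -> list[AlignmentSegment]:
    return [
        AlignmentSegment(
            r.query_genome, r.query_contig, int(r.qstart), int(r.qend),
            r.ref_contig, int(r.rstart), int(r.rend), r.strand,
        )
        for r in df.itertuples(index=False)
    ]


def stage_simulate(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.simulate
    rng = cfg.rng("simulate")
    comm = simulate_community(
        n_species=blk.n_species,
        pop_size=blk.pop_size,
        genome_length=blk.genome_length,
        mut_rate=blk.mut_rate,
        recomb_rate=blk.recomb_rate,
        tract_mean=blk.tract_mean,
        generations=blk.generations,
        sample_n=blk.sample_n,
        species_divergence=blk.species_divergence,
        sag_params=SagParams(
            breadth_mean=blk.breadth_mean,
            breadth_sd=blk.breadth_sd,
            block_mean=blk.block_mean,
            min_contig=blk.min_contig,
            contam_prob=blk.contam_prob,
        ),
        tnf_z_cutoff=cfg.mge.tnf_z_cutoff,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    assemblies, paths = [], []
    segments, genes, labels, ssu_records = [], [], [], []
    truth_tables: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ["mge_carriage", "spacer_origins", "ssu_edits", "sag_recovery", "mag_exclusions", "crispr_arrays"]
    }
    for sp in comm.species:
        for asm in sp.sags.assemblies + [sp.mag]:
            path = gdir / f"{asm.genome_id}.fasta"
            write_fasta(asm.contigs, path)
            assemblies.append(asm)
            paths.append(str(path.relative_to(outdir)))
        segments.extend(sp.sags.segments)
        segments.extend(sp.mag_segments)
        genes.append(sp.genes)
        labels.append(sp.sags.mge_labels)
        labels.append(
            pd.DataFrame(
                [
                    (c.id, sp.mag.genome_id, lab, ln, mid)
                    for c, lab, ln, mid in _mag_label_rows(sp)
                ],
                columns=["contig_id", "genome_id", "label", "length", "mge_id"],
            )
        )
        for cell_id, codes in sp.aug.ssu_seqs.items():
            from ._seq import decode

            ssu_records.append(SeqRecord(id=cell_id, seq=decode(codes)))
        pop_tag = sp.pop_id
        mut = sp.aug.truth.events.mutation_table()
        mut.insert(0, "pop_id", pop_tag)
        write_tsv(mut, tdir / f"mutations_{pop_tag}.tsv")
        tr = sp.aug.truth.events.tract_table()
        tr.insert(0, "pop_id", pop_tag)
        write_tsv(tr, tdir / f"tracts_{pop_tag}.tsv")
        for key, df in [
            ("mge_carriage", sp.aug.mge_carriage),
            ("spacer_origins", sp.aug.spacer_origins),
            ("ssu_edits", sp.aug.ssu_edits),
            ("sag_recovery", sp.sags.recovery),
            ("mag_exclusions", sp.mag_exclusions),
            ("crispr_arrays", sp.aug.crispr_truth),
        ]:
            if len(df):
                df = df.copy()
                df.insert(0, "pop_id", pop_tag)
                truth_tables[key].append(df)
    write_manifest(assemblies, paths, outdir / "manifest.tsv")
    write_tsv(_segments_frame(segments), outdir / "alignments.tsv")
    write_tsv(pd.concat(genes, ignore_index=True), outdir / "genes.tsv")
    write_tsv(pd.concat(labels, ignore_index=True), outdir / "mge_labels.tsv")
    write_fasta(ssu_records, outdir / "ssu.fasta")
    for key, frames in truth_tables.items():
        if frames:
            write_tsv(pd.concat(frames, ignore_index=True), tdir / f"{key}.tsv")
    _write_json(
        {"n_genomes": len(assemblies), "params": cfg.to_dict()["simulate"]},
        outdir / "simulate_summary.json",
    )


def _mag_label_rows(sp):
    rows = []
    for c in sp.mag.contigs:
        if c.id.startswith("mag_c"):
            continue
        mid = c.id.split("_", 1)[1]
        spec = next((m for m in sp.aug.pool_specs if m.mge_id == mid), None)
        if spec is not None:
            rows.append((c, spec.label, len(c), mid))
    return rows


def _load_genomes(outdir: Path):
    return read_manifest(outdir / "manifest.tsv")


def _species_groups(outdir: Path) -> dict[str, str]:
    df = read_tsv(outdir / "species_groups.tsv")
    return dict(zip(df["genome_id"], df["species_group"]))


def stage_ani(outdir: Path, cfg: PipelineConfig) -> None:
    genomes = _load_genomes(outdir)
    blk = cfg.ani
    matrix = ani_mod.ani_matrix(genomes, blk.frag_len, blk.kmer, blk.min_frag_frac, blk.band)
    labels = ani_mod.cluster_ani(genomes, threshold=blk.species_threshold, matrix=matrix)
    write_tsv(matrix, outdir / "ani_matrix.tsv")
    write_tsv(
        pd.DataFrame(
            {
                "genome_id": sorted(labels),
                "species_group": [labels[g] for g in sorted(labels)],
            }
        ),
        outdir / "species_groups.tsv",
    )
    sizes = pd.Series(list(labels.values())).value_counts().to_dict()
    _write_json({"n_groups": len(sizes), "group_sizes": sizes}, outdir / "ani_summary.json")


def _groups_with_sags(outdir: Path, min_sags: int = 3):
    genomes = _load_genomes(outdir)
    groups = _species_groups(outdir)
    by_group: dict[str, list] = {}
    for g in genomes:
        g.meta.species_group = groups[g.genome_id]
        by_group.setdefault(groups[g.genome_id], []).append(g)
    out = {}
    for gid, members in sorted(by_group.items()):
        n_sag = sum(1 for m in members if m.meta.kind == GenomeKind.SAG)
        if n_sag >= min_sags:
            out[gid] = members
    return out


def stage_snps(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.snp
    segments = _segments_from_frame(read_tsv(outdir / "alignments.tsv"))
    summary = {}
    for gid, members in _groups_with_sags(outdir).items():
        member_ids = {m.genome_id for m in members}
        ref_id = snp_mod.select_reference(members, blk.max_contamination)
        segs = [s for s in segments if s.query_genome in member_ids]
        matrix = snp_mod.build_allele_matrix(members, ref_id, segs)
        snps = snp_mod.call_snps(
            matrix, blk.min_called_cells, blk.min_called_frac, blk.min_minor_count
        )
        write_tsv(snps.to_frame(), outdir / f"snp_matrix_{gid}.tsv")
        summary[gid] = {
            "reference": ref_id,
            "n_cells": snps.n_cells,
            "n_sites": snps.n_sites,
            "n_conflicts": matrix.n_conflicts,
        }
    _write_json(summary, outdir / "snp_summary.json")


def _read_snp_matrix(path: Path) -> snp_mod.SnpMatrix:
    df = read_tsv(path)
    meta_cols = ["contig", "pos", "major", "minor", "minor_count", "called_count"]
    cells = [c for c in df.columns if c not in meta_cols]
    contig_names = sorted(df["contig"].unique())
    cidx = {c: i for i, c in enumerate(contig_names)}
    base = {b: i for i, b in enumerate("ACGT")}
    return snp_mod.SnpMatrix(
        reference_id="",
        cells=cells,
        contig_names=contig_names,
        site_contig=np.array([cidx[c] for c in df["contig"]]),
        site_pos=df["pos"].to_numpy(),
        major=np.array([base[b] for b in df["major"]], dtype=np.uint8),
        minor=np.array([base[b] for b in df["minor"]], dtype=np.uint8),
        minor_count=df["minor_count"].to_numpy(),
        called_count=df["called_count"].to_numpy(),
        geno=df[cells].to_numpy().T.astype(np.int8),
    )


def stage_ld(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.ld
    rng = cfg.rng("ld")
    bins = ld_mod.default_bins(blk.bin_min, blk.bin_max, blk.n_bins)
    summary = {}
    for path in sorted(outdir.glob("snp_matrix_*.tsv")):
        gid = path.stem.replace("snp_matrix_", "")
        snps = ld_mod.filter_maf(_read_snp_matrix(path), blk.min_maf)
        if snps.n_sites < 2:
            summary[gid] = {"ld50": None, "note": "too few SNP sites"}
            continue
        try:
            curve = ld_mod.ld_profile(snps, bins=bins, min_cells=blk.min_cells)
        except ValueError as e:
            summary[gid] = {"ld50": None, "note": str(e)}
            continue
        try:
            value = ld_mod.ld50(curve, blk.ld50_threshold, blk.min_pairs_per_bin)
        except ValueError as e:
            write_tsv(curve.to_frame(), outdir / f"ld_curve_{gid}.tsv")
            summary[gid] = {"ld50": None, "note": str(e)}
            continue
        write_tsv(curve.to_frame(), outdir / f"ld_curve_{gid}.tsv")
        boot = ld_mod.bootstrap_ld50(
            snps, n_boot=blk.n_boot, seed=int(rng.integers(0, 2**31 - 1)),
            bins=bins, min_cells=blk.min_cells, threshold=blk.ld50_threshold,
            min_pairs_per_bin=blk.min_pairs_per_bin,
        )
        if blk.write_pairs:
            dist, r2, ncells = ld_mod._all_pairs_r2(snps, blk.min_cells)
            write_tsv(
                pd.DataFrame({"distance": dist, "r2": r2, "n_cells": ncells}),
                outdir / f"ld_pairs_{gid}.tsv",
            )
        summary[gid] = {
            "ld50": value if isinstance(value, str) else round(float(value), 3),
            "ld50_upper_bound": curve.ld50_upper_bound,
            "ci_low": boot.ci_low,
            "ci_high": boot.ci_high,
            "sentinel_rate": boot.sentinel_rate,
            "secondary_unlinked_fraction_distance": _maybe(
                ld_mod.unlinked_fraction_distance, snps, blk.ld50_threshold, blk.min_cells
            ),
        }
    _write_json(summary, outdir / "ld50.json")
    # keep a stable alias for the per-species curves
    curves = sorted(outdir.glob("ld_curve_*.tsv"))
    if curves:
        (outdir / "ld_curve.tsv").write_text(curves[0].read_text())


def _maybe(fn, *args):
    try:
        v = fn(*args)
        return v if isinstance(v, str) else round(float(v), 3)
    except ValueError:
        return None


def stage_popstruct(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.popstruct
    rng = cfg.rng("popstruct")
    summary = {}
    for path in sorted(outdir.glob("snp_matrix_*.tsv")):
        gid = path.stem.replace("snp_matrix_", "")
        snps = _read_snp_matrix(path)
        if snps.n_sites < 2 or snps.n_cells < 4:
            summary[gid] = {"note": "too few sites or cells"}
            continue
        dm = snp_distance_robust(snps, blk.min_shared)
        if dm is None:
            summary[gid] = {"note": "insufficient shared sites"}
            continue
        tree = pop_mod.nj_tree(dm)
        (outdir / f"tree_{gid}.nwk").write_text(str(tree) if str(tree).endswith("\n") else str(tree))
        labels = pop_mod.cluster_cells(dm, blk.k_max)
        write_tsv(
            pd.DataFrame({"genome_id": dm.ids, "cluster": labels}),
            outdir / f"clusters_{gid}.tsv",
        )
        write_tsv(dm.to_frame(), outdir / f"distance_matrix_{gid}.tsv")
        conc = pop_mod.concordance_test(
            dm, tree, labels, n_perm=blk.n_perm,
            seed=int(rng.integers(0, 2**31 - 1)), distance=blk.distance,
        )
        summary[gid] = {"n_clusters": int(labels.max() + 1), "concordance": conc}
    _write_json(summary, outdir / "permanova.json")
    trees = sorted(outdir.glob("tree_*.nwk"))
    if trees:
        (outdir / "tree.nwk").write_text(trees[0].read_text())


def snp_distance_robust(snps: snp_mod.SnpMatrix, min_shared: int):
    """snp_distance, greedily dropping the worst-connected cells when some
    pairs share too few co-called sites."""
    current = snps
    for _ in range(snps.n_cells):
        try:
            return pop_mod.snp_distance(current, min_shared)
        except ValueError:
            shared = ((current.geno >= 0).astype(int) @ (current.geno >= 0).astype(int).T)
            bad_counts = (shared < min_shared).sum(axis=1)
            worst = int(np.argmax(bad_counts))
            keep = [i for i in range(current.n_cells) if i != worst]
            if len(keep) < 4:
                return None
            current = snp_mod.SnpMatrix(
                reference_id=current.reference_id,
                cells=[current.cells[i] for i in keep],
                contig_names=current.contig_names,
                site_contig=current.site_contig,
                site_pos=current.site_pos,
                major=current.major,
                minor=current.minor,
                minor_count=current.minor_count,
                called_count=current.called_count,
                geno=current.geno[keep],
            )
    return None


def stage_genefam(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.genefam
    rng = cfg.rng("genefam")
    genes_df = read_tsv(outdir / "genes.tsv")
    groups = _species_groups(outdir)
    genomes = _load_genomes(outdir)
    kinds = {g.genome_id: g.meta.kind.value for g in genomes}
    genes_df["group"] = genes_df["genome_id"].map(groups)
    all_fams = []
    summary = {}
    for gid, sub in sorted(genes_df.groupby("group")):
        genes = [
            genefam_mod.Gene(
                gene_id=r.gene_id, genome_id=r.genome_id, seq=r.seq,
                category=r.category, mge_flag=bool(r.mge_flag),
            )
            for r in sub.itertuples(index=False)
        ]
        fm = genefam_mod.greedy_cluster(genes, blk.identity, blk.coverage, kinds)
        filtered = genefam_mod.drop_singletons(fm, blk.min_genomes, blk.sag_only_rule)
        fam_table = fm.to_frame()
        fam_table.insert(0, "species_group", gid)
        all_fams.append(fam_table)
        write_tsv(fm.presence.reset_index(names="family_id"), outdir / f"presence_matrix_{gid}.tsv")
        rar = genefam_mod.rarefaction(
            filtered, mode=blk.rarefaction_mode, n_perm=blk.n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        write_tsv(rar, outdir / f"rarefaction_{gid}.tsv")
        mags = [g for g, k in kinds.items() if k == "MAG" and groups.get(g) == gid]
        entry = {
            "n_families": len(fm.families),
            "n_families_filtered": len(filtered.families),
        }
        if len(mags) == 1:
            comp = genefam_mod.compare_sag_mag(fm, mags[0], blk.min_genomes)
            write_tsv(
                pd.DataFrame(
                    [
                        {"family_id": f, "set": setname}
                        for setname in ("sag_only", "shared", "mag_only")
                        for f in comp[setname]
                    ]
                ),
                outdir / f"sag_mag_compare_{gid}.tsv",
            )
            entry.update(
                {
                    "sag_only": len(comp["sag_only"]),
                    "shared": len(comp["shared"]),
                    "mag_only": len(comp["mag_only"]),
                    "sag_only_mge_fraction": comp["sag_only_mge_fraction"],
                }
            )
        summary[gid] = entry
    write_tsv(pd.concat(all_fams, ignore_index=True), outdir / "families.tsv")
    _write_json(summary, outdir / "genefam_summary.json")


def stage_mge(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.mge
    rng = cfg.rng("mge")
    genomes = _load_genomes(outdir)
    labels = read_tsv(outdir / "mge_labels.tsv")
    carriage = mge_mod.carriage_table(genomes, labels, blk.min_len)
    write_tsv(carriage, outdir / "carriage.tsv")
    seq_of = {(g.genome_id, c.id): c.seq for g in genomes for c in g.contigs}
    lineage_of = {g.genome_id: g.meta.lineage for g in genomes}
    contigs = [
        (r.contig_id, lineage_of[r.genome_id], r.label, seq_of[(r.genome_id, r.contig_id)])
        for r in labels.itertuples(index=False)
        if (r.genome_id, r.contig_id) in seq_of
        and len(seq_of[(r.genome_id, r.contig_id)]) > blk.min_len
    ]
    tnf_rows = []
    circ_rows = []
    for cid, lineage, label, seq in contigs:
        vec = mge_mod.tnf(seq, cid)
        tnf_rows.append([cid, lineage, label] + list(vec.freq))
        is_circ, overlap = mge_mod.detect_circular(
            seq, blk.circular_min_overlap, blk.circular_max_mismatch
        )
        circ_rows.append({"contig_id": cid, "circular": is_circ, "overlap": overlap})
    if tnf_rows:
        ncol = len(tnf_rows[0]) - 3
        write_tsv(
            pd.DataFrame(tnf_rows, columns=["contig_id", "lineage", "label"] + [f"tnf{i}" for i in range(ncol)]),
            outdir / "tnf.tsv",
        )
    write_tsv(pd.DataFrame(circ_rows), outdir / "circularity.tsv")
    summary = {"n_mge_contigs": len(contigs), "n_circular": int(sum(r["circular"] for r in circ_rows))}
    lineages_with = {l for _c, l, _lab, _s in contigs}
    nonpro = [c for c in contigs if c[2] != "prophage"]
    by_lin = pd.Series([l for _c, l, _lab, _s in nonpro]).value_counts()
    if len(by_lin) >= 2 and (by_lin >= 2).sum() >= 2:
        keepable = set(by_lin[by_lin >= 2].index)
        subset = [c for c in nonpro if c[1] in keepable]
        f, p, nexcl = mge_mod.tnf_permanova(
            [(c, l, lab, s) for c, l, lab, s in contigs if l in keepable],
            n_perm=blk.n_perm, seed=int(rng.integers(0, 2**31 - 1)),
        )
        summary["tnf_permanova"] = {"F": f, "p": p, "n_prophage_excluded": nexcl}
    groups = mge_mod.group_mges_by_ani([(c[0], c[3]) for c in contigs], threshold=0.99)
    write_tsv(groups, outdir / "mge_groups.tsv")
    _write_json(summary, outdir / "tnf_permanova.json")


def stage_crispr(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.crispr
    genomes = _load_genomes(outdir)
    groups = _species_groups(outdir)
    for g in genomes:
        g.meta.species_group = groups.get(g.genome_id)
    sags = [g for g in genomes if g.meta.kind == GenomeKind.SAG]
    array_rows, spacer_rows, spacer_recs = [], [], []
    for g in sags:
        arrays = crispr_mod.find_arrays(
            g,
            repeat_len=(blk.repeat_len_min, blk.repeat_len_max),
            spacer_len=(blk.spacer_len_min, blk.spacer_len_max),
            min_repeats=blk.min_repeats,
            max_repeat_mismatch=blk.max_repeat_mismatch,
        )
        for ai, arr in enumerate(arrays):
            array_rows.append(
                {
                    "genome_id": g.genome_id,
                    "contig_id": arr.contig_id,
                    "start": arr.start,
                    "end": arr.end,
                    "n_repeats": arr.n_repeats,
                    "repeat_consensus": arr.repeat_consensus,
                    "n_spacers": len(arr.spacers),
                }
            )
            for si, (seq, s, e) in enumerate(arr.spacers):
                sid = f"{g.genome_id}_a{ai}_s{si}"
                spacer_rows.append(
                    {
                        "spacer_id": sid,
                        "genome_id": g.genome_id,
                        "contig_id": arr.contig_id,
                        "array_start": arr.start,
                        "array_end": arr.end,
                        "seq": seq,
                    }
                )
                spacer_recs.append(SeqRecord(id=sid, seq=seq))
    write_tsv(pd.DataFrame(array_rows), outdir / "arrays.tsv")
    write_fasta(spacer_recs, outdir / "spacers.fasta")
    spacers = pd.DataFrame(spacer_rows)
    if len(spacers):
        hits = crispr_mod.match_spacers(
            spacers, genomes, blk.max_mismatch, blk.exclusion_margin,
            {g.genome_id: groups.get(g.genome_id, "") for g in genomes},
        )
        write_tsv(crispr_mod.hits_to_frame(hits), outdir / "spacer_hits.tsv")
    else:
        write_tsv(crispr_mod.hits_to_frame([]), outdir / "spacer_hits.tsv")
    # spacer rarefaction per lineage
    by_lineage: dict[str, dict[str, set]] = {}
    lineage_of = {g.genome_id: g.meta.lineage for g in genomes}
    for r in spacer_rows:
        lin = lineage_of[r["genome_id"]]
        by_lineage.setdefault(lin, {}).setdefault(r["genome_id"], set()).add(r["seq"])
    rar_frames = []
    for lin, sets in sorted(by_lineage.items()):
        if len(sets) < 2:
            continue
        df = crispr_mod.spacer_rarefaction(sets)
        df.insert(0, "lineage", lin)
        rar_frames.append(df)
    if rar_frames:
        write_tsv(pd.concat(rar_frames, ignore_index=True), outdir / "spacer_rarefaction.tsv")
    n_with = len({r["genome_id"] for r in array_rows})
    _write_json(
        {
            "n_sags": len(sags),
            "n_sags_with_array": n_with,
            "fraction_with_array": n_with / len(sags) if sags else None,
            "n_spacers": len(spacer_rows),
        },
        outdir / "crispr_summary.json",
    )


def stage_primers(outdir: Path, cfg: PipelineConfig) -> None:
    blk = cfg.primers
    genomes = _load_genomes(outdir)
    lineage_of = {g.genome_id: g.meta.lineage for g in genomes}
    primers = primers_mod.PrimerSet(blk.fw, blk.rv, (blk.amplicon_min, blk.amplicon_max))
    results = [
        primers_mod.classify(
            rec.id, rec.seq, primers, blk.max_total_mm, blk.max_3prime_mm,
            blk.intron_excess, blk.fail_floor,
        )
        for rec in read_fasta(outdir / "ssu.fasta")
    ]
    table = primers_mod.results_to_frame(results, lineage_of)
    write_tsv(table, outdir / "amplifiability.tsv")
    spots = primers_mod.lineage_blindspot(table, blk.fail_frac_threshold)
    write_tsv(spots, outdir / "lineage_blindspots.tsv")
    _write_json(
        {
            "n_sequences": len(results),
            "fail_fraction": float((table["verdict"] != "pass").mean()) if len(table) else None,
            "n_flagged_lineages": int(spots["flagged"].sum()) if len(spots) else 0,
        },
        outdir / "primers_summary.json",
    )


_STAGE_FN = {
    "simulate": stage_simulate,
    "ani": stage_ani,
    "snps": stage_snps,
    "ld": stage_ld,
    "popstruct": stage_popstruct,
    "genefam": stage_genefam,
    "mge": stage_mge,
    "crispr": stage_crispr,
    "primers": stage_primers,
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    manifest: str | Path | None = None,
    stages: list[str] | None = None,
) -> Path:
    """Run the requested stages (default: all) over a working directory.

    With an external manifest the simulate stage is skipped and the
    manifest (plus alignments/genes/labels/ssu files beside it) must
    provide the stage inputs.  A stage failure halts the run with an
    error identifying the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGES)
    for s in stages:
        if s not in _STAGE_FN:
            raise ValueError(f"unknown stage {s!r}")
    if manifest is not None:
        stages = [s for s in stages if s != "simulate"]
        manifest = Path(manifest)
        if manifest.resolve() != (outdir / "manifest.tsv").resolve():
            (outdir / "manifest.tsv").write_text(Path(manifest).read_text())
    for s in STAGES:
        if s not in stages:
            continue
        cfg_stage = {"snps": "snp", "primers": "primers"}.get(s, s)
        config.log_stage(cfg_stage if hasattr(config, cfg_stage) else s)
        logger.info("running stage %s", s)
        try:
            _STAGE_FN[s](outdir, config)
        except Exception as e:
            raise RuntimeError(f"stage {s!r} failed on {outdir}: {e}") from e
    return outdir
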