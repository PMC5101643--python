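"""End-to-end orchestration: simulate → MLPA → ddPCR → breakpoints → popstats.

``run_pipeline`` executes the stages enabled in a :class:`RunConfig`,
writes every intermediate artefact under an output directory (FASTA,
CSV/TSV, JSON, Nexus) and returns a JSON-serializable report.  With a
fixed seed the report is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from athcnv import breakpoints as bp
from athcnv import popstats
from athcnv.ddpcr import DdpcrAssay, concordance
from athcnv.io import RunConfig, write_fasta
from athcnv.locus import default_locus_map, psv_intervals
from athcnv.mlpa import MlpaAssay
from athcnv.simulate import (
    panel_to_frame,
    simulate_ddpcr_wells,
    simulate_junction_amplicon,
    simulate_mlpa_peaks,
    simulate_panel,
    simulate_pseudogenome,
    simulate_reference,
    simulate_snp_matrix,
)

__all__ = ["run_pipeline", "stage_seeds"]

_STAGES = ("panel", "reference", "mlpa", "ddpcr", "pseudogenomes", "snps")


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage substream seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Run the full synthetic study and return the analysis report."""
    config = config or RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- synthesis -----------------------------------------------------
    panel = simulate_panel(config.panel, seed=seeds["panel"])
    truth = panel_to_frame(panel)
    reference, locus = simulate_reference(seed=seeds["reference"])
    peaks = simulate_mlpa_peaks(panel, config.panel, locus, seed=seeds["mlpa"])
    if out is not None:
        truth.to_csv(out / "panel_truth.csv")
        write_fasta(out / "reference.fa", [("reference", reference)])
        locus.to_json(out / "locus.json")
        peaks.to_csv(out / "mlpa_peaks.csv")

    # --- MLPA ----------------------------------------------------------
    mlpa_res = None
    if config.run_mlpa:
        assay = MlpaAssay(
            peaks,
            calibrator=config.calibrator_id,
            thresholds={
                "del": config.mlpa_del_threshold,
                "dup": config.mlpa_dup_threshold,
            },
            dupl3b_factor=config.dupl3b_factor,
            saturation=config.panel.mlpa_saturation,
        )
        mlpa_res = assay.fit()
        pattern_counts = (
            mlpa_res.calls["pattern"].value_counts().to_dict()
        )
        freq = popstats.genotype_frequencies(
            mlpa_res.calls.rename(columns={"pattern": "genotype_pattern"})
        )
        report["stages"]["mlpa"] = {
            "n_samples": len(mlpa_res.calls),
            "pattern_counts": {k: int(v) for k, v in sorted(pattern_counts.items())},
            "del2_percent": float(freq.loc["All", "del-2_pct"])
            if "del-2_pct" in freq.columns else 0.0,
            "qc_fail": int((mlpa_res.qc["status"] == "FAIL").sum()),
        }
        if out is not None:
            mlpa_res.to_csv(out / "mlpa_calls.csv")
            mlpa_res.qc.to_csv(out / "mlpa_qc.csv")

    # --- ddPCR ----------------------------------------------------------
    if config.run_ddpcr:
        wells = simulate_ddpcr_wells(panel, config.panel, seed=seeds["ddpcr"])
        dd_res = DdpcrAssay(wells, reference_assay=config.ddpcr_reference).fit()
        report["stages"]["ddpcr"] = {
            "n_samples": int(dd_res.estimates["sample"].nunique()),
        }
        if out is not None:
            wells.to_csv(out / "ddpcr_wells.csv", index=False)
            dd_res.to_csv(out / "ddpcr_estimates.csv")
        if mlpa_res is not None:
            conc = concordance(
                mlpa_res.calls, dd_res.estimates, mlpa_res.ratios
            )
            report["stages"]["ddpcr"]["concordance"] = {
                "categorical_agreement": conc["categorical_agreement"],
                "rank_correlation": conc["rank_correlation"],
                "n_comparisons": conc["n_comparisons"],
            }
            if out is not None:
                conc["table"].to_csv(out / "concordance.csv", index=False)

    # --- breakpoints ------------------------------------------------------
    if config.run_breakpoints:
        hits = bp.find_repeats(
            reference,
            chrom=locus.region.chrom,
            origin=locus.region.start,
        )
        del_ivs, dup_ivs, paint_rows = [], [], []
        for prof in panel:
            if prof.genotype_pattern not in ("del-2", "dupl-2"):
                continue
            jtype = (
                "deletion" if prof.genotype_pattern == "del-2"
                else "duplication"
            )
            jseq = simulate_junction_amplicon(prof, reference, locus)
            painting = bp.paint_junction(
                jseq, locus.lcr, junction_id=prof.accession_id,
                junction_type=jtype,
                flank_upstream_seqs=_flanks(reference, locus, "up"),
                flank_downstream_seqs=_flanks(reference, locus, "down"),
            )
            iv = bp.locate_breakpoint(painting, locus.lcr)
            (del_ivs if jtype == "deletion" else dup_ivs).append(iv)
            paint_rows.append({
                "junction": prof.accession_id,
                "type": jtype,
                "calls": painting.calls,
                "switch_lo": iv[0],
                "switch_hi": iv[1],
                "interval_index": bp.switch_interval_index(iv, locus.lcr),
                "conversions": ",".join(map(str, painting.conversion_sites)),
            })
        dsb = (
            bp.infer_dsb_region(del_ivs, dup_ivs, locus.lcr)
            if del_ivs and dup_ivs else None
        )
        report["stages"]["breakpoints"] = {
            "n_repeat_hits": len(hits),
            "n_junctions_painted": len(paint_rows),
            "del_switch_intervals": sorted(set(map(tuple, del_ivs))),
            "dup_switch_intervals": sorted(set(map(tuple, dup_ivs))),
            "dsb_region": list(dsb) if dsb else None,
        }
        if out is not None:
            pd.DataFrame(paint_rows).to_csv(
                out / "junction_painting.tsv", sep="\t", index=False
            )
            with open(out / "repeat_hits.bed", "w") as fh:
                for h in hits:
                    for iv in (h.interval_a, h.interval_b):
                        fh.write(
                            f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                            f"{h.orientation}_{h.percent_identity:.2f}\n"
                        )

    # --- popstats ---------------------------------------------------------
    if config.run_popstats:
        pg_seeds = np.random.SeedSequence(seeds["pseudogenomes"]).spawn(
            len(panel)
        )
        fractions = {}
        block = locus.block_region
        for prof, child in zip(panel, pg_seeds):
            pg = simulate_pseudogenome(
                prof, reference, locus,
                n_noise_rate=config.panel.pseudogenome_n_noise,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            fractions[prof.accession_id] = popstats.missingness_fraction(
                pg, block, locus.region
            )
        pred = {
            acc: popstats.predict_del2(
                f, config.del2_missingness_threshold
            )
            for acc, f in fractions.items()
        }
        truth_del2 = truth["genotype_pattern"] == "del-2"
        tp = sum(pred[a] and truth_del2[a] for a in pred)
        fp = sum(pred[a] and not truth_del2[a] for a in pred)
        n_del2 = int(truth_del2.sum())
        matrix, _ = simulate_snp_matrix(panel, config.panel, seed=seeds["snps"])
        filtered = popstats.filter_snps(
            matrix, min_maf=config.min_maf, max_missing=config.max_missing
        )
        ld = popstats.cnv_ld_scan(filtered, truth)
        freq = popstats.genotype_frequencies(truth, grouping="country")
        report["stages"]["popstats"] = {
            "del2_classifier": {
                "sensitivity": tp / n_del2 if n_del2 else None,
                "false_positives": fp,
                "n_del2_truth": n_del2,
                "predicted_frequency_pct": round(
                    100.0 * sum(pred.values()) / len(pred), 2
                ),
            },
            "n_snps_input": int(len(matrix)),
            "n_snps_filtered": int(len(filtered)),
            "max_snp_cnv_r2": float(np.nanmax(ld["max_r2"].to_numpy()))
            if len(ld) else None,
        }
        if out is not None:
            matrix.to_csv(out / "snp_matrix.tsv", sep="\t")
            filtered.to_csv(out / "snp_matrix_filtered.tsv", sep="\t")
            dist = popstats.pairwise_distance(filtered)
            popstats.write_nexus(filtered, dist, out / "snps.nex")
            ld.to_csv(out / "snp_cnv_r2.tsv", sep="\t")
            freq.to_csv(out / "genotype_frequencies.csv")

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        with open(out / "report.md", "w") as fh:
            fh.write(_markdown_report(report))
    return report


def _flanks(reference: str, locus, side: str, k: int = 30):
    region = locus.region
    lcr = locus.lcr

    def seg(a, b):  # genomic, 1-based inclusive
        return reference[a - region.start: b - region.start + 1]

    if side == "up":
        return (
            seg(lcr.left.start - k, lcr.left.start - 1),
            seg(lcr.right.start - k, lcr.right.start - 1),
        )
    return (
        seg(lcr.left.end + 1, lcr.left.end + k),
        seg(lcr.right.end + 1, lcr.right.end + k),
    )


def _markdown_report(report: dict) -> str:
    lines = [
        "# Locus CNV analysis report",
        "",
        f"- seed: {report['seed']}",
        f"- config hash: {report['config_hash']}",
        "",
    ]
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
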