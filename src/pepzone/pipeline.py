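"""End-to-end pipeline driver: design → quantify → map epitopes → serology
→ structure map, with reproducible seeded runs and TSV reports.

Every output table carries a header comment with the hash of the resolved
configuration, so byte-identical outputs certify an identical run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import antigenicity as ag
from . import array_quant as aq
from . import seqcore, serology, structure_map, synth
from .errors import PepzoneError

log = logging.getLogger("pepzone")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    out_dir: str = "pepzone_run"
    peptide_table: str | None = None  # None -> packaged β2GP1 table
    slide_image: str | None = None  # 16-bit PNG/TIFF; quantified if given
    slide_layout: str | None = None  # layout TSV accompanying slide_image
    reactivity: str | None = None  # TSV; None -> simulate
    elisa_panel: str | None = None  # TSV; None -> simulate
    structure_pdb: str | None = None  # PDB path; None -> simulate
    chain: str = "A"
    window_len: int = 15
    step: int = 4
    antigenicity_threshold: float = 0.5
    near_threshold_low: float = 0.45
    threshold_k: float = 2.0
    n_random: int = 15
    anchors: tuple[int, ...] = structure_map.DEFAULT_ANCHORS
    edge_delta: float = structure_map.DEFAULT_EDGE_DELTA
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PepzoneError(f"unknown config keys: {sorted(unknown)}")
        if "anchors" in raw:
            raw["anchors"] = tuple(raw["anchors"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # identifies the analysis, not where it lands
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pepzone {__version__} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary report dict.

    Stage errors are re-raised with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    report: dict = {"config_hash": h, "seed": config.seed}
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.info("pepzone %s run, config hash %s, seed %d", __version__, h, config.seed)

    try:
        stage = "design"
        table = seqcore.load_peptide_table(config.peptide_table)
        antigen = seqcore.stitch_peptides(table, seq_id="antigen")
        cfg = seqcore.TilingConfig(window_len=config.window_len, step=config.step)
        tiling = seqcore.annotate_domains(seqcore.tile_protein(antigen, cfg))
        seqcore.write_fasta(antigen, out / "antigen.fasta")
        _write_table(seqcore.peptides_to_frame(tiling), out / "tiling.tsv", h)
        report["n_peptides"] = len(tiling)
        report["antigen_length"] = len(antigen)

        stage = "quantify"
        if config.slide_image is not None:
            if config.slide_layout is None:
                raise PepzoneError("slide_image given without slide_layout")
            img = aq.read_image(config.slide_image)
            layout = aq.read_layout(config.slide_layout)
            quants = aq.measure_iod(img, layout)
            tmodel = aq.compute_threshold(
                quants, n_random=config.n_random, k=config.threshold_k, seed=config.seed
            )
            calls = aq.call_positive(quants, tmodel)
            qdf = aq.quants_to_frame(quants)
            _write_table(qdf, out / "spot_quants.tsv", h)
            _write_table(calls.astype(int).to_frame(), out / "spot_calls.tsv", h, index=True)
            report["quantify"] = {
                "threshold": tmodel.threshold,
                "n_positive": int(calls.sum()),
                "sampled_ids": list(tmodel.sampled_ids),
            }

        stage = "map-epitopes"
        if config.reactivity is not None:
            matrix = ag.read_reactivity(config.reactivity)
        else:
            matrix, truth = synth.gen_reactivity(
                synth.CohortSpec(seed=config.seed, n_peptides=len(tiling))
            )
            with open(out / "reactivity_truth.json", "w") as jf:
                json.dump(truth, jf, indent=1, default=str)
            ag.write_reactivity(matrix, out / "reactivity.tsv")
        profile = ag.recognition_frequency(matrix)
        zones = ag.detect_zones(profile, config.antigenicity_threshold, peptides=tiling)
        near = ag.near_threshold_report(
            profile, config.near_threshold_low, config.antigenicity_threshold
        )
        counts, means = ag.serum_breadth(matrix)
        zone_df = ag.zones_to_frame(zones)
        _write_table(zone_df, out / "zones.tsv", h)
        _write_table(
            profile.fractions.rename("fraction").to_frame(), out / "profile.tsv", h, index=True
        )
        _write_table(counts.to_frame(), out / "breadth.tsv", h, index=True)
        report["zones"] = zone_df.to_dict("records")
        report["near_threshold_peptides"] = near
        report["mean_breadth"] = {str(k): float(v) for k, v in means.items()}

        stage = "serology"
        if config.elisa_panel is not None:
            panel = pd.read_csv(config.elisa_panel, sep="\t", comment="#", index_col=0)
        else:
            panel, _ = synth.gen_elisa(synth.ElisaMixtureSpec(seed=config.seed))
            _write_table(panel, out / "elisa_panel.tsv", h, index=True)
        flags = serology.classify_positivity(panel)
        _write_table(flags.astype(int), out / "elisa_positivity.tsv", h, index=True)
        corr = serology.pearson_ci(panel["anti_b2gp1_iga"], panel["anti_d45_iga"])
        split = serology.split_correlation(
            panel["anti_b2gp1_iga"].to_numpy(), panel["anti_d45_iga"].to_numpy()
        )
        report["serology"] = {
            "n_positive": {c: int(flags[c].sum()) for c in flags.columns},
            "r_anti_d45": corr.r,
            "r_ci": [corr.ci_low, corr.ci_high],
            "split_boundary": split.boundary,
            "split_r_high": split.corr_a.r,
            "split_r_low": split.corr_b.r,
            "split_informative": split.informative,
        }

        stage = "structure-map"
        if config.structure_pdb is not None:
            model = structure_map.read_structure(
                Path(config.structure_pdb).read_text(), chain=config.chain
            )
        else:
            # plant the detected zones and the anchor epitope on face L
            spans = [(z.span_start, z.span_end) for z in zones if z.span_start]
            spans.append((min(config.anchors), max(config.anchors)))
            model, _ = synth.gen_structure(
                n_res=len(antigen),
                shape="fishhook",
                l_side_spans=spans,
                seed=config.seed,
            )
        plane = structure_map.fit_face_plane(
            model, anchors=config.anchors, edge_delta=config.edge_delta
        )
        labels = structure_map.classify_faces(model, plane)
        zone_spans = {
            f"zone{i + 1}": (z.span_start, z.span_end)
            for i, z in enumerate(zones)
            if z.span_start is not None
        }
        if zone_spans:
            faces = structure_map.zone_face_fraction(zone_spans, labels)
            _write_table(faces, out / "zone_faces.tsv", h)
            report["zone_faces"] = faces.to_dict("records")
        _write_table(labels.to_frame(), out / "face_labels.tsv", h, index=True)
        structure_map.write_face_overlay(model, labels, out / "face_overlay.pdb")
    except PepzoneError as exc:
        raise PepzoneError(f"[stage {stage}] {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    with open(out / "report.json", "w") as jf:
        json.dump(report, jf, indent=1, default=str)
    return report
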