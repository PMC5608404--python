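"""Pipeline orchestration: run the full barcode evaluation from one config.

Stages (in method order): read or simulate the aligned input, build K2P
distance matrices, best-close-match identification, tree-based
discrimination (when a tree is given; otherwise a neighbor-joining fixture
tree), the species-by-habitat haplotype table, per-species PCoA, the
inland-vs-combined Mann-Whitney comparison, and the theta-resampling
sampling-sufficiency curves. Every output is a TSV stamped with the config
hash and master seed in a sidecar manifest; outputs carry no timestamps so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    distance,
    group_stats,
    haplotype,
    identification,
    ordination,
    saturation,
    sequence_io,
    tree_discrimination,
)
from .errors import ConfigError, HalobarcodeError
from .synthetic_data import HaplotypeSpec, SimulationSpec, SpeciesSpec, simulate_dataset

logger = logging.getLogger("halobarcode.pipeline")

DEFAULTS = {
    "threshold": 0.03,  # BCM distance threshold (3%)
    "threshold_percentile": None,  # derive from data instead when set
    "support_cutoff": 0.95,
    "confidence": 0.9999,
    "replicates": 20,
    "saturation_min_n": 3,
    "site_mode": "pairwise_deletion",
    "gap_mode": "exclude_sites",
    "singletons": "exclude",
    "rule": "stable",
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _spec_from_config(sim: dict, seed: int) -> SimulationSpec:
    species = tuple(
        SpeciesSpec(
            name=s["name"],
            n_inland=int(s["n_inland"]),
            n_coastal=int(s["n_coastal"]),
            haplotypes=tuple(
                HaplotypeSpec(
                    divergence=float(h["divergence"]),
                    availability=h.get("availability", "both"),
                    weight=float(h.get("weight", 1.0)),
                )
                for h in s["haplotypes"]
            ),
        )
        for s in sim["species"]
    )
    return SimulationSpec(
        species=species,
        length=int(sim.get("length", 600)),
        kappa=float(sim.get("kappa", 2.0)),
        interspecific_divergence=float(sim.get("interspecific_divergence", 0.15)),
        seed=seed,
        locus=sim.get("locus", "ITS"),
        require_barcode_gap=bool(sim.get("require_barcode_gap", True)),
    )


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage; returns a manifest dict (also written to disk).

    ``config`` must contain ``seed`` (seeds are mandatory, never implicit)
    and either a ``simulate`` block or ``fasta`` + ``metadata`` paths.
    """
    if "seed" not in config:
        raise ConfigError("config must set an explicit integer 'seed'")
    seed = int(config["seed"])
    cfg = {**DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "seed": seed, "outputs": {}, "log": {}}

    def _save(name: str, table: pd.DataFrame) -> None:
        sequence_io.write_table(table, outdir / name)
        manifest["outputs"][name] = name

    stage = "input"
    try:
        if "simulate" in cfg:
            sim = simulate_dataset(_spec_from_config(cfg["simulate"], seed))
            aset = sim.sequences
            sequence_io.write_alignment(
                aset, outdir / "alignment.fasta", outdir / "metadata.tsv"
            )
            _save("truth_assignments.tsv", sim.assignments)
            _save("truth_theta.tsv", sim.expected_theta)
            _save("truth_haplotypes.tsv", sim.group_haplotypes)
            manifest["outputs"]["alignment.fasta"] = "alignment.fasta"
            manifest["outputs"]["metadata.tsv"] = "metadata.tsv"
        else:
            if "fasta" not in cfg or "metadata" not in cfg:
                raise ConfigError("config needs 'simulate' or 'fasta'+'metadata'")
            aset = sequence_io.read_alignment(
                cfg["fasta"], cfg["metadata"], cfg.get("locus")
            )
        manifest["log"]["n_sequences"] = len(aset)
        manifest["log"]["n_species"] = len(aset.species_names())

        stage = "distances"
        matrix = distance.pairwise_matrix(aset, "K2P", cfg["site_mode"])
        sequence_io.write_matrix(matrix, outdir / "k2p_matrix.tsv")
        manifest["outputs"]["k2p_matrix.tsv"] = "k2p_matrix.tsv"
        manifest["log"]["n_undefined_pairs"] = matrix.n_undefined_pairs

        stage = "identification"
        species_map = aset.species_map
        if cfg.get("threshold_percentile") is not None:
            thr = identification.intraspecific_threshold(
                matrix, species_map, float(cfg["threshold_percentile"])
            )
        else:
            thr = float(cfg["threshold"])
        summary = identification.best_close_match(
            matrix, species_map, thr, locus=aset.locus
        )
        _save("bcm_queries.tsv", summary.as_frame())
        _save("bcm_summary.tsv", summary.summary_frame())
        manifest["log"]["n_uncomparable"] = summary.n_uncomparable

        stage = "tree_discrimination"
        if "tree" in cfg:
            stree = sequence_io.read_tree(cfg["tree"], species_map=species_map)
            missing_support, unrooted = "fail", False
        else:  # fixture tree from the matrix; NJ is unrooted and unsupported
            stree = tree_discrimination.neighbor_joining(matrix, species_map)
            missing_support, unrooted = "full", True
        rate, per_species = tree_discrimination.discrimination_rate(
            stree,
            support_cutoff=float(cfg["support_cutoff"]),
            singletons=cfg["singletons"],
            outgroup=tuple(cfg.get("outgroup", ())),
            missing_support=missing_support,
            unrooted=unrooted,
        )
        _save(
            "tree_discrimination.tsv",
            pd.DataFrame(
                [{"species": sp, "status": st} for sp, st in sorted(per_species.items())]
            ),
        )
        manifest["log"]["discrimination_rate_pct"] = rate

        stage = "haplotypes"
        hap_table = haplotype.haplotype_table(aset, cfg["gap_mode"])
        _save("haplotype_table.tsv", hap_table)

        stage = "pcoa"
        frames = []
        for sp in aset.species_names():
            sub = aset.filter_species(sp)
            if len(sub) < 3:
                continue
            m = matrix.submatrix(sub.sample_ids)
            if m.n_undefined_pairs:
                logger.warning("pcoa: skipping %s (undefined distances)", sp)
                continue
            res = ordination.pcoa(m)
            frames.append(res.as_frame(species=aset.species_map, groups=aset.group_map))
        if frames:
            _save("pcoa_coordinates.tsv", pd.concat(frames, ignore_index=True))

        stage = "mann_whitney"
        mw_rows = []
        for sp in aset.species_names():
            ids = [s.sample_id for s in aset.samples if s.species == sp]
            inland = [s for s in ids if aset.group_map[s] == "inland"]
            if len(inland) < 2 or len(ids) < 3 or len(inland) == len(ids):
                continue
            x = group_stats.intraspecific_distances(
                matrix.submatrix(inland), species_map
            )
            y = group_stats.intraspecific_distances(
                matrix.submatrix(ids), species_map
            )
            if len(x) == 0 or len(y) == 0:
                continue
            r = group_stats.mann_whitney(x, y)
            mw_rows.append(
                {
                    "species": sp,
                    "U": r.U,
                    "z": r.z,
                    "p_two_sided": r.p_two_sided,
                    "n1": r.n1,
                    "n2": r.n2,
                    "method": r.method,
                    "significant": "*" if r.p_two_sided < 0.01 else "",
                }
            )
        if mw_rows:
            _save("mann_whitney.tsv", pd.DataFrame(mw_rows))

        stage = "saturation"
        sat_frames = []
        nmin_rows = []
        for si, sp in enumerate(aset.species_names()):
            ids = [s.sample_id for s in aset.samples if s.species == sp]
            if len(ids) < int(cfg["saturation_min_n"]) or len(ids) < 3:
                continue
            sub = matrix.submatrix(ids)
            if sub.n_undefined_pairs:
                logger.warning("saturation: skipping %s (undefined distances)", sp)
                continue
            # one stream per species, derived from master seed + species index
            sp_seed = int(
                np.random.SeedSequence([seed, si]).generate_state(1)[0] % (2**31)
            )
            curve = saturation.saturation_curve(
                matrix,
                ids,
                species=sp,
                replicates=int(cfg["replicates"]),
                seed=sp_seed,
                confidence=float(cfg["confidence"]),
                rule=cfg["rule"],
            )
            sat_frames.append(curve.as_frame())
            nmin_rows.append(
                {
                    "species": sp,
                    "N": curve.N,
                    "full_theta": curve.full_theta,
                    "ci_high": curve.ci_high,
                    "n_min": -1 if curve.n_min is None else curve.n_min,
                }
            )
        if sat_frames:
            _save("saturation_curves.tsv", pd.concat(sat_frames, ignore_index=True))
            _save("saturation_summary.tsv", pd.DataFrame(nmin_rows))
    except HalobarcodeError as exc:
        raise HalobarcodeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
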