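"""Configured, logged orchestration of the analysis stages.

``run_water_pipeline`` executes permutation reduction, mobility,
interface classification, solvent-entropy bookkeeping and water-bridge
detection in order on one trajectory; ``run_selex_pipeline`` runs k-mer
counting, fold change, relative enrichment, local maxima and optional
temperature trends over read pools.  Every numeric threshold is carried
in :class:`RunConfig` and echoed into each output file's metadata;
a :class:`RunManifest` records the seed, config hash and per-output
checksums so that identical configurations reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants, __version__
from .bridges import bridge_occupancy, trajectory_bridges
from .entropy import interface_entropy_summary, per_water_entropy
from .interface import (InterfaceCriterion, InterfaceMode, classify_low_mobility,
                        find_interfacial_waters)
from .permutation import compute_mobility, permute_water_identities
from .selex import (EnrichmentReport, ReadPool, compute_enrichment, count_kmers,
                    report_to_rows, temperature_profile)
from .trajectory import EntityClass, Trajectory, TrajectoryError, read_pdb_models

logger = logging.getLogger("hydrodna")


@dataclass
class RunConfig:
    # inputs
    trajectory_pdb: str | None = None
    signal_fastq: str | None = None
    background_fastq: str | None = None
    out_dir: str = "hydrodna_out"
    seed: int = 0
    # thresholds (defaults mirror the constants table)
    interface_cutoff_A: float = constants.INTERFACE_CUTOFF_INSTANTANEOUS_A
    interface_mode: str = "instantaneous"
    mobility_rmsf_threshold_A: float = constants.RMSF_LOW_MOBILITY_A
    hbond_da_cutoff_A: float = constants.HBOND_DA_CUTOFF_A
    hbond_dha_min_deg: float = constants.HBOND_DHA_MIN_DEG
    bridge_max_order: int = constants.BRIDGE_MAX_ORDER
    bridge_stability_frac: float = constants.BRIDGE_STABILITY_FRACTION
    entropy_temperature_K: float = constants.TEMPERATURE_K
    entropy_s_bulk: float = constants.S_BULK_J_PER_K_MOL
    selex_k: int = 6
    selex_reference_kmer: str = constants.REFERENCE_KMER
    selex_strand: str = "both_strands"
    selex_pseudocount: float = 0.0
    # stage toggles
    run_bridges: bool = True
    bridges_distance_only: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # fields that name inputs/outputs rather than analysis conditions;
    # excluded from the config hash so identical analyses on identical
    # data match regardless of where results are written
    _PATH_FIELDS = ("trajectory_pdb", "signal_fastq", "background_fastq",
                    "out_dir")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in self._PATH_FIELDS}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Plain-text ``key = value`` config; CLI overrides win."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise TrajectoryError(f"config line {lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                key = key.replace(".", "_")
                if key not in fields:
                    raise TrajectoryError(f"config line {lineno}: unknown key {key!r}")
                values[key] = _coerce(raw, getattr(cls(), key))
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes", "on")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload, manifest: RunManifest,
                config: RunConfig) -> None:
    thresholds = {k: v for k, v in config.to_dict().items()
                  if k not in RunConfig._PATH_FIELDS}
    doc = {"metadata": {"tool": "hydrodna", "version": __version__,
                        "config": thresholds},
           "data": payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=_json_default) + "\n")
    manifest.outputs[path.name] = _sha256(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(path: Path, rows: list[dict], manifest: RunManifest,
               config: RunConfig) -> None:
    lines = [f"# hydrodna {__version__} config={config.config_hash()} "
             f"seed={config.seed}"]
    if rows:
        cols = list(rows[0])
        lines.append("\t".join(cols))
        for r in rows:
            lines.append("\t".join(str(r[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")
    manifest.outputs[path.name] = _sha256(path)


def run_water_pipeline(config: RunConfig,
                       traj: Trajectory | None = None) -> dict:
    """permute -> mobility -> interface -> entropy -> bridges.

    ``traj`` may be passed directly (e.g. a synthetic trajectory);
    otherwise ``config.trajectory_pdb`` is read.  Returns the stage
    results and writes TSV/JSON twins plus a manifest under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_hash=config.config_hash(),
                           seed=config.seed)
    if traj is None:
        if not config.trajectory_pdb:
            raise TrajectoryError("no trajectory given (trajectory_pdb unset)")
        traj = read_pdb_models(config.trajectory_pdb)

    results: dict = {}
    if not traj.topology.water_molecules:
        manifest.warnings.append("no waters: water stages produce empty reports")
        _write_json(out / "interface_report.json", {"sites": []}, manifest, config)
        _write_json(out / "entropy_summary.json",
                    {"N": 0, "S_avg": None, "S_total": 0.0,
                     "S_bulk": config.entropy_s_bulk, "delta_S_solv": 0.0},
                    manifest, config)
        _write_tsv(out / "bridges.tsv", [], manifest, config)
        manifest.write(out / "manifest.json")
        return {"manifest": manifest, "interface_report": None,
                "entropy_summary": None, "bridge_table": []}

    t0 = time.perf_counter()
    permuted = permute_water_identities(traj)
    manifest.timings_s["permute"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mobility = compute_mobility(permuted)
    _write_tsv(out / "mobility.tsv", mobility.to_rows(), manifest, config)
    manifest.timings_s["mobility"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    criterion = InterfaceCriterion(
        cutoff=config.interface_cutoff_A,
        mode=config.interface_mode,
        partner_a=traj.topology.selection(EntityClass.PROTEIN),
        partner_b=traj.topology.selection(EntityClass.DNA),
    )
    if criterion.mode is InterfaceMode.MEAN_POSITION:
        interfacial, fractions = find_interfacial_waters(
            mobility, criterion, reference_frame=traj.frames[0])
    else:
        interfacial, fractions = find_interfacial_waters(permuted, criterion)
    report = classify_low_mobility(
        mobility, interfacial, config.mobility_rmsf_threshold_A,
        interfacial_fractions=fractions, criterion=criterion)
    results["interface_report"] = report
    _write_json(out / "interface_report.json", {
        "cutoff_A": config.interface_cutoff_A,
        "mode": config.interface_mode,
        "rmsf_threshold_A": config.mobility_rmsf_threshold_A,
        "n_interfacial": report.n_interfacial,
        "n_low_mobility": report.n_low_mobility,
        "low_mobility_percentage": report.low_mobility_percentage,
        "sites": [dataclasses.asdict(s) for s in report.sites],
    }, manifest, config)
    manifest.timings_s["interface"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    entropies = per_water_entropy(permuted, temperature=config.entropy_temperature_K)
    summary = interface_entropy_summary(entropies, interfacial,
                                        s_bulk=config.entropy_s_bulk)
    results["per_water_entropy"] = entropies
    results["entropy_summary"] = summary
    _write_tsv(out / "per_water_entropy.tsv",
               [dataclasses.asdict(e) for e in entropies], manifest, config)
    _write_json(out / "entropy_summary.json", summary.to_dict(), manifest, config)
    manifest.timings_s["entropy"] = time.perf_counter() - t0

    bridge_table = []
    if config.run_bridges:
        t0 = time.perf_counter()
        has_h = any(w.hydrogen_indices for w in traj.topology.water_molecules)
        if not has_h and not config.bridges_distance_only:
            manifest.warnings.append(
                "waters carry no hydrogens; bridge stage skipped "
                "(set bridges_distance_only to opt in to O...O detection)")
        else:
            per_frame = trajectory_bridges(
                traj, cutoff=config.hbond_da_cutoff_A,
                angle_min=config.hbond_dha_min_deg,
                max_order=config.bridge_max_order,
                distance_only=not has_h)
            bridge_table = bridge_occupancy(
                per_frame, traj.n_frames, config.bridge_stability_frac)
            _write_tsv(out / "bridges.tsv", [{
                "protein_residue": "/".join(map(str, b.protein_residue)),
                "nucleotide": "/".join(map(str, b.nucleotide)),
                "fraction_total": b.occurrence_fraction,
                **{f"fraction_order_{k}": v
                   for k, v in sorted(b.fraction_by_order.items())},
                "stable": b.stable,
                "representative_chain": ",".join(map(str, b.representative_chain or ())),
            } for b in bridge_table], manifest, config)
        manifest.timings_s["bridges"] = time.perf_counter() - t0
    results["bridge_table"] = bridge_table
    results["mobility"] = mobility
    results["permuted"] = permuted

    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    return results


def run_selex_pipeline(config: RunConfig,
                       signal: ReadPool | None = None,
                       background: ReadPool | None = None,
                       temperature_pools: dict[float, ReadPool] | None = None,
                       ) -> dict:
    """count -> fold change -> relative enrichment -> maxima
    (-> temperature trends when a per-temperature mapping is given)."""
    from .selex import read_fastq
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_hash=config.config_hash(),
                           seed=config.seed)
    if background is None:
        if not config.background_fastq:
            raise TrajectoryError("no background pool given")
        background = read_fastq(config.background_fastq, cycle=0)
    bg_table = count_kmers(background, config.selex_k, config.selex_strand)

    results: dict = {}
    if temperature_pools:
        reports: dict[float, EnrichmentReport] = {}
        for t, pool in sorted(temperature_pools.items()):
            table = count_kmers(pool, config.selex_k, config.selex_strand)
            reports[t] = compute_enrichment(
                table, bg_table, config.selex_reference_kmer,
                config.selex_pseudocount, condition={"temperature_C": t})
        trends = temperature_profile(reports)
        results["reports"] = reports
        results["trends"] = trends
        _write_tsv(out / "temperature_trends.tsv", [{
            "kmer": tr.kmer, "spearman": tr.spearman,
            "trend_sign": tr.trend_sign,
            **{f"pct_{int(t)}C": v
               for t, v in zip(tr.temperatures, tr.enrichment_pct)},
        } for tr in trends], manifest, config)
    else:
        if signal is None:
            if not config.signal_fastq:
                raise TrajectoryError("no signal pool given")
            signal = read_fastq(config.signal_fastq, cycle=1)
        table = count_kmers(signal, config.selex_k, config.selex_strand)
        report = compute_enrichment(table, bg_table,
                                    config.selex_reference_kmer,
                                    config.selex_pseudocount)
        results["report"] = report
        _write_tsv(out / "enrichment.tsv", report_to_rows(report),
                   manifest, config)
        _write_json(out / "enrichment.json", {
            "reference_kmer": report.reference_kmer,
            "local_maxima": report.local_maxima(),
            "entries": report_to_rows(report),
        }, manifest, config)

    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    return results
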