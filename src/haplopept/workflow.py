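"""End-to-end orchestration with plain-file stage boundaries.

Stages run in dependency order (simulate -> build-db -> digest ->
classify -> coverage -> qc); every stage reads and writes plain files
(FASTA/TSV/MGF/JSON) so each can also be run and inspected on its own.
A run manifest records the configuration hash, seed, output checksums
and row counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as cls_mod
from . import coverage as cov_mod
from . import digestion, haplotype_db, psm_qc, synthetic_data
from .predictors import ToyPredictor
from .records import PeptideOccurrence, ProteinRecord, Substitution

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build_db", "digest", "classify", "coverage", "qc")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; defaults match the study conditions

    (2 missed cleavages, 8-40 residue peptides, 10 ppm peak matching,
    1% PSM-level FDR).
    """

    outdir: str = "haplopept_run"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic data
    n_proteins: int = 20
    protein_length_range: tuple = (150, 300)
    substitution_density: float = 1.5
    haplotypes_per_protein: int = 3
    planted_pairs: int = 2
    n_contaminants: int = 3
    # digestion
    max_missed: int = 2
    length_min: int = 8
    length_max: int = 40
    proline_rule: bool = True
    # QC
    tolerance_ppm: float = 10.0
    fdr_threshold: float = 0.01
    noise_level: float = 0.2
    decoy_fraction: float = 0.3
    max_qc_peptides: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg = dataclasses.replace(
            cfg,
            stages=tuple(cfg.stages),
            protein_length_range=tuple(cfg.protein_length_range),
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["protein_length_range"] = list(d["protein_length_range"])
        return d

    @property
    def length_range(self) -> tuple[int, int]:
        return (self.length_min, self.length_max)

    def synthetic_config(self) -> synthetic_data.SyntheticConfig:
        return synthetic_data.SyntheticConfig(
            n_proteins=self.n_proteins,
            protein_length_range=self.protein_length_range,
            substitution_density=self.substitution_density,
            haplotypes_per_protein=self.haplotypes_per_protein,
            planted_pairs=self.planted_pairs,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _row_count(path: Path) -> int:
    text = path.read_text()
    if not text:
        return 0
    lines = text.count("\n")
    if path.suffix == ".tsv":
        lines -= 1  # header
    return lines


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} requires {name}, which was not produced by an "
            "earlier stage"
        )
    return path


def stage_simulate(config: RunConfig, out: Path) -> None:
    refs, haps, manifest = synthetic_data.generate_proteome(config.synthetic_config())
    conts = synthetic_data.generate_contaminants(config.n_contaminants, config.seed)
    haplotype_db.write_fasta(refs, out / "reference.fasta")
    haplotype_db.write_haplotype_table(haps, out / "haplotypes.tsv")
    haplotype_db.write_fasta(conts, out / "contaminants.fasta")
    manifest.save(out / "ground_truth.json")


def stage_build_db(config: RunConfig, out: Path) -> None:
    refs = haplotype_db.read_fasta(_require(out, "reference.fasta", "build_db"))
    haps = haplotype_db.read_haplotype_table(
        _require(out, "haplotypes.tsv", "build_db")
    )
    cont_path = out / "contaminants.fasta"
    conts = haplotype_db.read_fasta(cont_path) if cont_path.exists() else []
    targets = haplotype_db.build_target_database(refs, haps, conts)
    haplotype_db.write_fasta(targets, out / "targets.fasta")
    decoys = haplotype_db.generate_decoys(
        targets,
        seed=config.seed,
        proline_rule=config.proline_rule,
        max_missed=config.max_missed,
        length_range=config.length_range,
    )
    haplotype_db.write_fasta(decoys, out / "decoys.fasta")


def write_peptide_table(occurrences, path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tpeptide\tstart\tend\tmissed_cleavages\tsubstitutions\n")
        for occ in occurrences:
            subs = ";".join(s.notation() for s in occ.substitutions)
            fh.write(
                f"{occ.accession}\t{occ.sequence}\t{occ.start}\t{occ.end}\t"
                f"{occ.missed_cleavages}\t{subs}\n"
            )


def read_peptide_table(path, records: dict[str, ProteinRecord]) -> list[PeptideOccurrence]:
    out = []
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for row in df.itertuples():
        rec = records[row.accession]
        subs = tuple(
            Substitution.parse(t) for t in str(row.substitutions).split(";") if t
        )
        out.append(
            PeptideOccurrence(
                sequence=row.peptide,
                accession=row.accession,
                start=int(row.start),
                end=int(row.end),
                missed_cleavages=int(row.missed_cleavages),
                substitutions=subs,
                gene_id=rec.gene_id,
                kind=rec.kind,
                parent_accession=rec.parent_accession,
            )
        )
    return out


def stage_digest(config: RunConfig, out: Path) -> None:
    targets = haplotype_db.read_fasta(_require(out, "targets.fasta", "digest"))
    occurrences = digestion.digest_all(
        targets,
        max_missed=config.max_missed,
        length_range=config.length_range,
        proline_rule=config.proline_rule,
    )
    write_peptide_table(occurrences, out / "peptides.tsv")


def _load_classified(config: RunConfig, out: Path, stage: str):
    targets = haplotype_db.read_fasta(_require(out, "targets.fasta", stage))
    records = {r.accession: r for r in targets}
    occurrences = read_peptide_table(
        _require(out, "peptides.tsv", stage), records
    )
    index = cls_mod.build_peptide_index(occurrences)
    classifications = cls_mod.classify_peptides(index)
    haps = [
        haplotype_db.haplotype_from_record(r)
        for r in targets
        if r.kind == "haplotype"
    ]
    refs = [r for r in targets if r.kind == "reference"]
    return records, refs, haps, classifications


def reference_frequencies(haplotypes) -> dict[str, float]:
    """Reference-haplotype frequency: 1 minus the summed haplotype shares."""
    totals: dict[str, float] = {}
    for hap in haplotypes:
        totals[hap.parent_accession] = totals.get(hap.parent_accession, 0.0) + hap.frequency
    return {acc: 1.0 - total for acc, total in totals.items()}


def stage_classify(config: RunConfig, out: Path) -> None:
    _, _, haps, classifications = _load_classified(config, out, "classify")
    cls_mod.classification_table(classifications).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    disc = cls_mod.substitution_discoverability(
        classifications, haps, reference_frequencies(haps)
    )
    cls_mod.discoverability_table(disc).to_csv(
        out / "discoverability.tsv", sep="\t", index=False
    )


def stage_coverage(config: RunConfig, out: Path) -> None:
    _, refs, _, classifications = _load_classified(config, out, "coverage")
    partition = cov_mod.residue_coverage(refs, classifications)
    partition.to_frame().to_csv(out / "coverage.tsv", sep="\t", index=False)


def stage_qc(config: RunConfig, out: Path) -> None:
    records, refs, haps, classifications = _load_classified(config, out, "qc")
    occurrences = read_peptide_table(_require(out, "peptides.tsv", "qc"), records)
    by_pep: dict[str, PeptideOccurrence] = {}
    for occ in occurrences:
        if occ.kind != "contaminant":
            by_pep.setdefault(occ.sequence, occ)
    rng = np.random.default_rng(config.seed)
    chosen = sorted(by_pep)
    if len(chosen) > config.max_qc_peptides:
        idx = rng.choice(len(chosen), size=config.max_qc_peptides, replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    predictor = ToyPredictor()
    psms, spectra, psm_manifest = synthetic_data.simulate_psms(
        [by_pep[p] for p in chosen],
        predictor,
        noise_level=config.noise_level,
        decoy_fraction=config.decoy_fraction,
        seed=config.seed,
    )
    synthetic_data.write_mgf(
        spectra, out / "spectra.mgf", synthetic_data.psm_pepmass(psms)
    )
    truth_path = out / "ground_truth.json"
    if truth_path.exists():
        truth = synthetic_data.GroundTruthManifest.load(truth_path)
        truth.planted_true_psm_ids = psm_manifest.planted_true_psm_ids
        truth.save(truth_path)

    scored, confident = psm_qc.target_decoy_qvalues(
        psms, threshold=config.fdr_threshold
    )
    angular = np.full(len(scored), np.nan)
    for i, row in enumerate(scored.itertuples()):
        observed = spectra[scored.index[i]]
        predicted = predictor.predict_fragments(row.peptide)
        scaled = psm_qc.scale_observed(observed, predicted)
        vectors, _ = psm_qc.match_peaks(
            scaled, predicted, tolerance_ppm=config.tolerance_ppm
        )
        angular[i] = psm_qc.angular_similarity(vectors)
    calibration = scored.index.isin(confident.index)
    rt_dev = psm_qc.rt_deviation(
        scored["rt_observed"].to_numpy(),
        scored["rt_predicted"].to_numpy(),
        calibration,
    )
    psm_qc.qc_table(scored, angular, rt_dev).to_csv(
        out / "psms_qc.tsv", sep="\t", index=False
    )
    confident = scored.loc[confident.index]
    confident.to_csv(out / "psms_confident.tsv", sep="\t", index=False)

    report = cov_mod.identified_coverage(
        set(confident["peptide"]), refs, classifications
    )
    report["identified_per_protein"].to_csv(
        out / "coverage_identified.tsv", sep="\t", index=False
    )
    cov_mod.summarize_identified_substitutions(confident, classifications).to_csv(
        out / "substitutions_identified.tsv", sep="\t", index=False
    )
    cov_mod.heterozygosity_evidence(confident, classifications, haps).to_csv(
        out / "heterozygosity.tsv", sep="\t", index=False
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build_db": stage_build_db,
    "digest": stage_digest,
    "classify": stage_classify,
    "coverage": stage_coverage,
    "qc": stage_qc,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages in dependency order; returns the run directory."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("haplopept").addHandler(handler)
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, out)
    finally:
        logging.getLogger("haplopept").removeHandler(handler)
        handler.close()
    config_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": config.seed,
        "outputs": {},
    }
    for path in sorted(out.iterdir()):
        if path.name in {"run_manifest.json", "run.log"} or path.is_dir():
            continue
        manifest["outputs"][path.name] = {
            "sha256": _sha256(path),
            "rows": _row_count(path),
        }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
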