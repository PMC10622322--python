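"""Synthetic proteomes, haplotypes, contaminants and simulated PSMs.

The generator emulates the inputs of a haplotype-aware proteogenomic
study: reference proteins, phased haplotypes carrying amino acid
substitutions above a minor-allele-frequency floor (default 1%),
contaminants, and simulated spectra with planted true and decoy
matches. A ground-truth manifest records what was planted so every
downstream stage can be checked exactly.

Two construction rules make the manifest exact rather than approximate:

* each *planted pair* of substitutions shares a single cleavage-free
  tryptic window (optionally with a K->E substitution destroying an
  internal cleavage site, so the reference digests into two fragments
  where the haplotype yields one), guaranteeing multivariant peptides;
* every other pair of substitutions within one haplotype is separated
  by at least 3 cleavage sites on the haplotype sequence, so no peptide
  with up to 2 missed cleavages can contain both. Multivariant peptides
  therefore arise from planted pairs only, and their expected sequences
  can be enumerated locally around each window.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mgf as pymgf

from .psm_qc import (
    MISSING_PREDICTION,
    MATCHED,
    Spectrum,
    angular_similarity,
    match_peaks,
)
from .predictors import FragmentRtPredictor, precursor_mz
from .records import (
    ConfigurationError,
    Haplotype,
    PeptideOccurrence,
    ProteinRecord,
    Substitution,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K and R boosted to 10% each so tryptic peptides land in the 8-40 window
AA_PROBS = np.array([0.1 if a in "KR" else 0.8 / 18 for a in AA])
_NON_KRP = list("ACDEFGHILMNQSTVWY")

_MIN_SEPARATING_SITES = 3  # > max missed cleavages


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic proteome.

    ``substitution_density`` is substitutions per 100 residues;
    ``frequency_distribution`` bounds the total population share of the
    non-reference haplotypes per protein (the remainder goes to the
    reference haplotype); ``cleavage_site_loss_rate`` is the proportion
    of substitutions replacing a cleavage-site K/R;
    ``planted_pairs`` is the number of guaranteed multivariant windows.
    """

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (150, 300)
    substitution_density: float = 1.5
    haplotypes_per_protein: int = 3
    frequency_distribution: tuple[float, float] = (0.25, 0.75)
    min_allele_frequency: float = 0.01
    cleavage_site_loss_rate: float = 0.1
    planted_pairs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid protein_length_range")
        if self.substitution_density < 0:
            raise ConfigurationError("substitution_density must be >= 0")
        if self.substitution_density == 0 and self.cleavage_site_loss_rate > 0:
            raise ConfigurationError(
                "cleavage_site_loss_rate > 0 requires substitution_density > 0"
            )
        if self.haplotypes_per_protein < 0:
            raise ConfigurationError("haplotypes_per_protein must be >= 0")
        if not (0 < self.min_allele_frequency <= 1):
            raise ConfigurationError("min_allele_frequency must be in (0, 1]")
        if not (0 <= self.cleavage_site_loss_rate <= 1):
            raise ConfigurationError("cleavage_site_loss_rate must be in [0, 1]")
        flo, fhi = self.frequency_distribution
        if not (0 < flo <= fhi < 1):
            raise ConfigurationError("frequency_distribution bounds must satisfy 0 < lo <= hi < 1")
        if self.planted_pairs < 0:
            raise ConfigurationError("planted_pairs must be >= 0")
        if self.planted_pairs > self.n_proteins:
            raise ConfigurationError("planted_pairs cannot exceed n_proteins")
        if self.planted_pairs > 0 and self.haplotypes_per_protein > 0 and lo < 80:
            raise ConfigurationError(
                "planting multivariant windows requires proteins of >= 80 residues"
            )


@dataclass
class GroundTruthManifest:
    """What the generator planted, for exact downstream verification."""

    planted_multivariant_peptides: list[dict] = field(default_factory=list)
    planted_substitution_classes: dict[str, str] = field(default_factory=dict)
    planted_true_psm_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_multivariant_peptides": self.planted_multivariant_peptides,
            "planted_substitution_classes": self.planted_substitution_classes,
            "planted_true_psm_ids": self.planted_true_psm_ids,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_multivariant_peptides=d["planted_multivariant_peptides"],
            planted_substitution_classes=d["planted_substitution_classes"],
            planted_true_psm_ids=d["planted_true_psm_ids"],
        )


# ---------------------------------------------------------------------------
# local cleavage helpers (kept independent of the digestion module so the
# manifest can serve as an oracle for it)


def _sites(seq: str) -> list[int]:
    last = len(seq) - 1
    return [
        i
        for i, r in enumerate(seq)
        if r in "KR" and i < last and seq[i + 1] != "P"
    ]


def _fragments(seq: str) -> list[tuple[int, int]]:
    bounds = [0] + [s + 1 for s in _sites(seq)] + [len(seq)]
    return list(zip(bounds[:-1], bounds[1:]))


def _separating_sites(seq: str, pos_a: int, pos_b: int) -> int:
    """Cleavage sites separating two 1-based residue positions."""
    a, b = sorted((pos_a - 1, pos_b - 1))
    return sum(1 for s in _sites(seq) if a <= s <= b - 1)


def _spans_containing_fragment(
    frags: list[tuple[int, int]], f: int, max_missed: int = 2
) -> list[tuple[int, int]]:
    spans = []
    for mc in range(max_missed + 1):
        for j in range(mc + 1):
            i0 = f - j
            if i0 < 0 or i0 + mc >= len(frags):
                continue
            spans.append((frags[i0][0], frags[i0 + mc][1]))
    return spans


def _apply(seq: str, subs: Sequence[tuple[int, str, str]]) -> str:
    chars = list(seq)
    for pos, _ref, alt in subs:
        chars[pos - 1] = alt
    return "".join(chars)


# ---------------------------------------------------------------------------
# proteome generation


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(AA, size=length, p=AA_PROBS))


def _carve_window(
    seq: list[str], rng: np.random.Generator, style: str
) -> tuple[int, int, list[tuple[int, str, str]]]:
    """Rewrite a region of the reference into a controlled tryptic window.

    Returns (window start, window end, planted substitutions as
    (1-based position, ref, alt)). ``style`` is ``plain`` (cleavage-free
    interior, two ordinary substitutions) or ``site_loss`` (an internal
    K whose K->E substitution removes the cleavage site, merging two
    reference fragments into one haplotype peptide).
    """
    length = len(seq)
    win_len = int(rng.integers(12, 19))
    ws = int(rng.integers(20, length - win_len - 20))
    we = ws + win_len
    seq[ws - 1] = "R"
    for i in range(ws, we - 1):
        seq[i] = str(rng.choice(_NON_KRP))
    seq[we - 1] = "R"
    if seq[we] == "P":
        seq[we] = str(rng.choice(_NON_KRP))
    interior = list(range(ws, we - 1))
    if style == "site_loss":
        kpos = ws + win_len // 2
        seq[kpos] = "K"
        sub_positions = [
            int(p) for p in rng.choice(
                [i for i in interior if i != kpos], size=1, replace=False
            )
        ]
        subs = [(kpos + 1, "K", "E")]
    else:
        sub_positions = [
            int(p) for p in rng.choice(interior, size=2, replace=False)
        ]
        subs = []
    for p in sub_positions:
        alts = [a for a in _NON_KRP if a != seq[p]]
        subs.append((p + 1, seq[p], str(rng.choice(alts))))
    return ws, we, sorted(subs)


def _sample_frequencies(
    rng: np.random.Generator, n: int, bounds: tuple[float, float], maf: float
) -> np.ndarray:
    for _ in range(1000):
        share = rng.uniform(*bounds)
        freqs = share * rng.dirichlet(np.ones(n))
        if freqs.min() >= maf and 1.0 - share > 0:
            return freqs
    share = rng.uniform(*bounds)
    return np.full(n, share / n)  # deterministic fallback


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[Haplotype], GroundTruthManifest]:
    """Generate reference proteins, phased haplotypes and the manifest.

    Deterministic under ``config.seed``: identical configs yield
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    references: list[ProteinRecord] = []
    haplotypes: list[Haplotype] = []
    manifest = GroundTruthManifest()

    n_hap = config.haplotypes_per_protein
    planted_total = config.planted_pairs if n_hap > 0 else 0
    windows_per_protein = [0] * config.n_proteins
    for w in range(planted_total):
        windows_per_protein[w % config.n_proteins] += 1

    for idx in range(config.n_proteins):
        accession = f"P{idx + 1:04d}"
        gene_id = f"G{idx + 1:04d}"
        lo, hi = config.protein_length_range
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)

        planted: list[tuple[int, int, list[tuple[int, str, str]]]] = []
        for w in range(windows_per_protein[idx]):
            style = "site_loss" if (idx + w) % 2 else "plain"
            planted.append(_carve_window(seq, rng, style))
        ref_seq = "".join(seq)
        references.append(
            ProteinRecord(accession=accession, sequence=ref_seq, gene_id=gene_id)
        )
        if n_hap == 0:
            continue

        # substitution specs per haplotype: planted windows go to h1
        hap_subs: list[list[tuple[int, str, str]]] = [[] for _ in range(n_hap)]
        blocked: set[int] = set()
        for ws, we, subs in planted:
            hap_subs[0].extend(subs)
            blocked.update(range(ws - 1, we + 1))
        used_positions = {p - 1 for _, _, subs in planted for p, _, _ in subs}

        n_random = int(round(config.substitution_density / 100.0 * length))
        for _ in range(n_random):
            h = int(rng.integers(0, n_hap))
            want_loss = rng.random() < config.cleavage_site_loss_rate
            for _attempt in range(100):
                pos0 = int(rng.integers(0, length))
                if pos0 in used_positions or pos0 in blocked:
                    continue
                ref = ref_seq[pos0]
                if want_loss != (ref in "KR"):
                    continue
                alts = [a for a in _NON_KRP if a != ref]
                alt = str(rng.choice(alts))
                trial = hap_subs[h] + [(pos0 + 1, ref, alt)]
                hap_seq = _apply(ref_seq, trial)
                ok = all(
                    _separating_sites(hap_seq, pos0 + 1, other[0])
                    >= _MIN_SEPARATING_SITES
                    for other in hap_subs[h]
                )
                if ok:
                    hap_subs[h].append((pos0 + 1, ref, alt))
                    used_positions.add(pos0)
                    break

        freqs = _sample_frequencies(
            rng, n_hap, config.frequency_distribution, config.min_allele_frequency
        )
        for h in range(n_hap):
            subs = tuple(
                Substitution(
                    position=pos,
                    ref_residue=ref,
                    alt_residue=alt,
                    variant_id=f"var_{accession}_{pos}",
                    allele_frequency=float(freqs[h]),
                )
                for pos, ref, alt in sorted(hap_subs[h])
            )
            haplotypes.append(
                Haplotype(
                    haplotype_id=f"h{h + 1}",
                    parent_accession=accession,
                    substitutions=subs,
                    frequency=float(freqs[h]),
                )
            )

        # manifest bookkeeping (local enumeration, no digestion module)
        hap1_seq = _apply(ref_seq, hap_subs[0]) if hap_subs else ref_seq
        for ws, we, subs in planted:
            frags = _fragments(hap1_seq)
            positions = [p for p, _, _ in subs]
            frag_idx = [
                f
                for f, (a, b) in enumerate(frags)
                if all(a <= p - 1 < b for p in positions)
            ]
            assert len(frag_idx) == 1, "planted pair must share one fragment"
            peptides = sorted(
                {
                    hap1_seq[a:b]
                    for a, b in _spans_containing_fragment(frags, frag_idx[0])
                    if 8 <= b - a <= 40
                }
            )
            for pep in peptides:
                manifest.planted_multivariant_peptides.append(
                    {
                        "peptide": pep,
                        "protein_id": accession,
                        "haplotype_id": "h1",
                        "positions": positions,
                    }
                )
            for pos, ref, alt in subs:
                manifest.planted_substitution_classes[
                    f"{accession}:{pos}{ref}>{alt}"
                ] = "multi_only"
        for h in range(n_hap):
            hseq = _apply(ref_seq, hap_subs[h])
            frags = _fragments(hseq)
            planted_keys = {
                f"{accession}:{pos}{ref}>{alt}"
                for _, _, subs in planted
                for pos, ref, alt in subs
            }
            for pos, ref, alt in hap_subs[h]:
                key = f"{accession}:{pos}{ref}>{alt}"
                if key in planted_keys:
                    continue
                f = next(
                    i for i, (a, b) in enumerate(frags) if a <= pos - 1 < b
                )
                discoverable = any(
                    8 <= b - a <= 40
                    for a, b in _spans_containing_fragment(frags, f)
                )
                manifest.planted_substitution_classes[key] = (
                    "single_only" if discoverable else "not_discoverable"
                )
    return references, haplotypes, manifest


def generate_contaminants(n: int, seed: int = 0) -> list[ProteinRecord]:
    """Random contaminant records with accessions disjoint from references."""
    if n < 0:
        raise ConfigurationError("contaminant count must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(80, 200))
        out.append(
            ProteinRecord(
                accession=f"CONT{i + 1:03d}",
                sequence="".join(_random_sequence(rng, length)),
                kind="contaminant",
            )
        )
    return out


# ---------------------------------------------------------------------------
# PSM simulation


def _corrupt(
    predicted: Spectrum, noise_level: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed peak list: prediction + noise, jitter and spurious peaks."""
    known = ~np.isnan(predicted.intensity)
    base = float(np.median(predicted.intensity[known])) if known.any() else 1.0
    intensity = predicted.intensity.copy()
    intensity[~known] = base  # unpredicted ions are still present in the sample
    if noise_level > 0:
        intensity = intensity * rng.lognormal(0.0, noise_level, size=intensity.size)
        jitter = rng.uniform(-10e-6, 10e-6, size=predicted.mz.size) * noise_level
        mz = predicted.mz * (1.0 + jitter)
        n_spurious = int(rng.poisson(noise_level * predicted.mz.size))
        if n_spurious:
            smz = rng.uniform(predicted.mz.min(), predicted.mz.max(), n_spurious)
            sint = base * rng.lognormal(-1.0, 0.5, n_spurious)
            mz = np.concatenate([mz, smz])
            intensity = np.concatenate([intensity, sint])
    else:
        mz = predicted.mz.copy()
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    keep = np.concatenate([[True], np.diff(mz) > 0])
    return mz[keep], intensity[keep]


def _match_score(observed: Spectrum, predicted: Spectrum) -> tuple[float, float]:
    """Search-score surrogate: angular similarity weighted by matched share."""
    vectors, annotations = match_peaks(observed, predicted)
    sim = angular_similarity(vectors)
    n_obs = len(observed)
    matched = sum(
        1 for c in annotations.observed if c in (MATCHED, MISSING_PREDICTION)
    )
    frac = matched / n_obs if n_obs else 0.0
    base = sim if np.isfinite(sim) else 0.5
    return base * frac, sim


def simulate_psms(
    peptides: Sequence[PeptideOccurrence],
    predictor: FragmentRtPredictor,
    noise_level: float = 0.2,
    decoy_fraction: float = 0.3,
    seed: int = 0,
    samples: Sequence[str] = ("S1", "S2", "S3"),
) -> tuple[pd.DataFrame, list[Spectrum], GroundTruthManifest]:
    """Simulate spectra with true target matches and planted decoy matches.

    Every unique peptide yields one true PSM whose observed spectrum is
    the corrupted prediction of that peptide; planted incorrect matches
    pair a corrupted spectrum with a shuffled decoy peptide.
    ``decoy_fraction`` is the fraction of all PSMs that are planted
    incorrect matches. Scores are higher in distribution for true
    matches. The returned manifest lists the true PSM identifiers.
    """
    if noise_level < 0:
        raise ConfigurationError("noise_level must be >= 0")
    if not (0 <= decoy_fraction < 1):
        raise ConfigurationError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    unique: dict[str, PeptideOccurrence] = {}
    for occ in peptides:
        unique.setdefault(occ.sequence, occ)
    pep_list = sorted(unique)
    if not pep_list:
        raise ValueError("no peptides to simulate")
    n_true = len(pep_list)
    n_decoy = int(round(decoy_fraction / (1.0 - decoy_fraction) * n_true))
    rows: list[dict] = []
    spectra: list[Spectrum] = []
    manifest = GroundTruthManifest()
    counter = 0

    def _observe(source_pep: str, psm_id: str) -> Spectrum:
        mz, inten = _corrupt(
            predictor.predict_fragments(source_pep), noise_level, rng
        )
        rt_obs = predictor.predict_rt(source_pep) + float(
            rng.normal(0.0, 120.0 * noise_level)
        )
        return Spectrum(
            mz=mz, intensity=inten, retention_time=rt_obs, identifier=psm_id
        )

    def _emit(observed: Spectrum, pep: str, accessions: str, label: str) -> None:
        nonlocal counter
        counter += 1
        score, _sim = _match_score(observed, predictor.predict_fragments(pep))
        spectra.append(observed)
        rows.append(
            {
                "spectrum_id": observed.identifier,
                "peptide": pep,
                "accessions": accessions,
                "sample_id": samples[counter % len(samples)],
                "score": score,
                "label": label,
                "rt_observed": observed.retention_time,
                "rt_predicted": predictor.predict_rt(pep),
            }
        )

    for pep in pep_list:
        observed = _observe(pep, f"psm{counter:05d}")
        manifest.planted_true_psm_ids.append(observed.identifier)
        _emit(observed, pep, unique[pep].accession, "target")
    target_set = set(pep_list)
    for _ in range(n_decoy):
        source = pep_list[int(rng.integers(0, n_true))]
        observed = _observe(source, f"psm{counter:05d}")
        # the decoy assigned to a spectrum is the best-scoring of a few
        # shuffled permutations of the source peptide, mimicking how
        # target-decoy competition picks the decoy sharing the most
        # fragment masses with the spectrum
        best_pep, best_score = None, -1.0
        for _attempt in range(5):
            chars = list(source[:-1])
            rng.shuffle(chars)
            candidate = "".join(chars) + source[-1]
            if candidate == source or candidate in target_set:
                continue
            score, _sim = _match_score(
                observed, predictor.predict_fragments(candidate)
            )
            if score > best_score:
                best_pep, best_score = candidate, score
        if best_pep is None:  # e.g. homopolymeric source; fall back to reversal
            best_pep = source[:-1][::-1] + source[-1]
        _emit(observed, best_pep, "decoy_" + unique[source].accession, "decoy")
    return pd.DataFrame(rows), spectra, manifest


# ---------------------------------------------------------------------------
# file output


def write_mgf(spectra: Sequence[Spectrum], path, pepmass: dict | None = None) -> None:
    """Write observed spectra as MGF (TITLE = identifier, RTINSECONDS)."""
    entries = []
    for sp in spectra:
        params = {
            "title": sp.identifier,
            "pepmass": (pepmass or {}).get(sp.identifier, 0.0),
        }
        if sp.retention_time is not None:
            params["rtinseconds"] = sp.retention_time
        entries.append(
            {
                "m/z array": sp.mz,
                "intensity array": sp.intensity,
                "params": params,
            }
        )
    pymgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    out = []
    with pymgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            rt = params.get("rtinseconds")
            out.append(
                Spectrum(
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    retention_time=float(rt) if rt is not None else None,
                    identifier=str(params.get("title", "")),
                )
            )
    return out


def psm_pepmass(psms: pd.DataFrame, charge: int = 2) -> dict[str, float]:
    return {
        row.spectrum_id: precursor_mz(row.peptide, charge)
        for row in psms.itertuples()
    }
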