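"""Ground-truth-labelled synthetic inputs for every analysis stage.

The generators emulate the data the downstream modules expect:

* phalloidin intensity profiles along a myofibril — a train of
  rectangle + half-Gaussian units with an optional central Z-disk bump and
  additive iid Gaussian noise;
* splice-junction read mixtures (multinomial over canonical / alternative /
  intron-retention events) and exon inclusion/exclusion counts consistent
  with a chosen true PSI;
* toy transcript models (FASTA + GFF3) whose canonical splice is guaranteed
  PTC-free, built by codon-aware sampling;
* single-twitch force traces (linear rise, exponential decay).

Every generator routes all randomness through one ``numpy`` Generator seeded
from the spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .filament_metrics import FilamentMeasurement, thin_filament_length
from .mechanics import ForceTrace
from .profile_fit import HWHM_FACTOR, IntensityProfile, SarcomereUnitFit
from .splicing import ExonCountRecord, JunctionLocus, TranscriptModel

_SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# sarcomere profiles

@dataclass(frozen=True)
class ProfileSimSpec:
    """Conditions for one simulated profile train.

    Defaults reproduce a physiological 3-dpf zebrafish myofibril: sarcomere
    length 2.0 um, thin filament ~1.0 um (plateau 1.65 um with 0.15 um
    flanks), sampled at 0.05 um/px with 2% additive noise.
    """

    n_units: int = 8
    sarcomere_length: float = 2.0     # um
    rect_width: float = 1.65          # um, plateau full width
    sigma_left: float = 0.15          # um
    sigma_right: float = 0.15         # um
    amplitude: float = 1.0            # AU
    baseline: float = 0.1             # AU
    zbump_amplitude: float = 0.0      # AU, bump at plateau centre
    zbump_sigma: float = 0.08         # um
    pixel_size: float = 0.05          # um
    noise_sd: float = 0.02            # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("need at least one unit")
        if min(self.rect_width, self.sigma_left, self.sigma_right,
               self.zbump_sigma, self.pixel_size) <= 0:
            raise ValueError("widths, sigmas and pixel_size must be positive")
        if self.noise_sd < 0 or self.zbump_amplitude < 0:
            raise ValueError("noise_sd and zbump_amplitude must be >= 0")
        if self.rect_width >= self.sarcomere_length:
            raise ValueError("plateaus collide: rect_width must be < sarcomere_length")


def profile_spec_for_tf(tf_um: float, sigma: float = 0.15, **kwargs) -> ProfileSimSpec:
    """Spec whose ground-truth thin-filament length equals ``tf_um``."""
    width = 2.0 * (tf_um - HWHM_FACTOR * sigma)
    return ProfileSimSpec(rect_width=width, sigma_left=sigma, sigma_right=sigma,
                          **kwargs)


def generate_profile_train(
    spec: ProfileSimSpec,
) -> tuple[IntensityProfile, list[SarcomereUnitFit], list[FilamentMeasurement]]:
    """Simulate a noisy train of sarcomere units with attached ground truth.

    The noiseless, bump-free curve is pixel-exactly the sum of
    ``profile_fit.eval_unit_model`` over the returned truth units (shared
    closed form), so fits can be scored against exact truth.
    """
    rng = np.random.default_rng(spec.seed)
    margin = spec.sarcomere_length
    total = 2.0 * margin + (spec.n_units - 1) * spec.sarcomere_length
    x = np.arange(0.0, total + spec.pixel_size / 2.0, spec.pixel_size)
    centers = margin + spec.sarcomere_length * np.arange(spec.n_units)
    y = np.full_like(x, spec.baseline)
    for c in centers:
        d = x - c
        excess = np.maximum(np.abs(d) - spec.rect_width / 2.0, 0.0)
        sigma = np.where(d < 0, spec.sigma_left, spec.sigma_right)
        y += spec.amplitude * np.exp(-(excess ** 2) / (2.0 * sigma ** 2))
        if spec.zbump_amplitude > 0:
            y += spec.zbump_amplitude * np.exp(-(d ** 2) / (2.0 * spec.zbump_sigma ** 2))
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=x.shape)
    profile = IntensityProfile(positions=x, intensities=y, pixel_size=spec.pixel_size)
    truth_units = [SarcomereUnitFit(center=float(c), rect_width=spec.rect_width,
                                    amplitude=spec.amplitude, baseline=spec.baseline,
                                    sigma_left=spec.sigma_left,
                                    sigma_right=spec.sigma_right)
                   for c in centers]
    truth_meas = [FilamentMeasurement(tf_length=thin_filament_length(u),
                                      sl=spec.sarcomere_length, unit_index=i)
                  for i, u in enumerate(truth_units)]
    return profile, truth_units, truth_meas


# ---------------------------------------------------------------------------
# splicing counts

@dataclass(frozen=True)
class SpliceSimSpec:
    """Conditions for simulated junction and exon-count tables.

    ``event_frequencies`` maps event labels to probabilities (must include
    the reserved labels ``canonical`` and/or ``intron_retention`` as needed;
    any other label is an alternative junction).  ``true_psi`` maps exon ids
    to inclusion fractions in [0, 1].
    """

    event_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"canonical": 0.0, "alt_acceptor_34": 0.187,
                                 "alt_acceptor_3": 0.054, "intron_retention": 0.759})
    total_junction_reads: int = 10_000
    exon_length: int = 100            # bp
    read_length: int = 150            # bp
    true_psi: Mapping[str, float] = field(
        default_factory=lambda: {"exon_1": 0.95, "exon_2": 0.5, "exon_3": 0.1})
    depth: int = 2_000                # informative reads per exon
    alt_offsets: Optional[Mapping[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.event_frequencies.values()) - 1.0) > 1e-12:
            raise ValueError("event frequencies must sum to 1")
        if any(p < 0 for p in self.event_frequencies.values()):
            raise ValueError("event frequencies must be non-negative")
        if self.total_junction_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be >= 0")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if any(not 0.0 <= p <= 1.0 for p in self.true_psi.values()):
            raise ValueError("true_psi values must be fractions in [0, 1]")


def simulate_junction_counts(
    spec: SpliceSimSpec,
) -> tuple[list[ExonCountRecord], JunctionLocus]:
    """Draw junction reads multinomially and exon counts binomially.

    Exon inclusion reads are drawn so that the *length-normalized* PSI
    estimator is consistent for ``true_psi``: the inclusion probability is
    psi*(L+r-1) / (psi*(L+r-1) + (1-psi)*(r-1)).
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.event_frequencies)
    probs = np.array([spec.event_frequencies[k] for k in labels], dtype=float)
    counts = rng.multinomial(spec.total_junction_reads, probs)
    by_label = dict(zip(labels, (int(c) for c in counts)))
    alts = []
    k = 0
    for label in labels:
        if label in ("canonical", "intron_retention"):
            continue
        k += 1
        offset = (spec.alt_offsets or {}).get(label, k)
        alts.append((label, offset, by_label[label]))
    locus = JunctionLocus(locus_id="locus_sim",
                          canonical_reads=by_label.get("canonical", 0),
                          alternative_junctions=tuple(alts),
                          retention_reads=by_label.get("intron_retention", 0))
    w_in = spec.exon_length + spec.read_length - 1
    w_ex = spec.read_length - 1
    records = []
    for i, (exon_id, p_psi) in enumerate(spec.true_psi.items(), start=1):
        denom = p_psi * w_in + (1.0 - p_psi) * w_ex
        p_inc = 1.0 if denom == 0 else p_psi * w_in / denom
        ir = int(rng.binomial(spec.depth, p_inc))
        records.append(ExonCountRecord(exon_id=exon_id, exon_index=i,
                                       exon_length=spec.exon_length,
                                       read_length=spec.read_length,
                                       inclusion_reads=ir,
                                       exclusion_reads=spec.depth - ir))
    return records, locus


# ---------------------------------------------------------------------------
# toy transcripts

def generate_toy_transcript(exon_lengths: Sequence[int],
                            intron_lengths: Sequence[int],
                            seed: int = 0) -> TranscriptModel:
    """Random plus-strand gene model whose canonical mRNA is one clean ORF.

    The spliced mRNA starts with ATG, ends with a stop codon, and contains
    no internal in-frame stop (codon-aware sampling, so construction never
    fails).  Introns of length >= 4 carry canonical GT...AG ends.
    """
    exon_lengths = [int(v) for v in exon_lengths]
    intron_lengths = [int(v) for v in intron_lengths]
    if len(exon_lengths) < 2:
        raise ValueError("need at least two exons")
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one intron between consecutive exons")
    if min(exon_lengths + intron_lengths) < 1:
        raise ValueError("all lengths must be positive")
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise ValueError("total exonic (CDS) length must be divisible by 3")
    rng = np.random.default_rng(seed)
    n_codons = total // 3
    if n_codons < 2:
        raise ValueError("CDS too short for start + stop")
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    mrna = "ATG" + "".join(_SENSE_CODONS[i] for i in body) \
        + _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    exon_seqs = []
    pos = 0
    for L in exon_lengths:
        exon_seqs.append(mrna[pos:pos + L])
        pos += L
    intron_seqs = []
    for L in intron_lengths:
        inner = "".join("ACGT"[i] for i in rng.integers(4, size=max(L - 4, 0)))
        intron_seqs.append(("GT" + inner + "AG") if L >= 4
                           else "".join("ACGT"[i] for i in rng.integers(4, size=L)))
    genomic = []
    exons = []
    at = 0
    for k, ex in enumerate(exon_seqs):
        exons.append((at + 1, at + len(ex)))
        genomic.append(ex)
        at += len(ex)
        if k < len(intron_seqs):
            genomic.append(intron_seqs[k])
            at += len(intron_seqs[k])
    return TranscriptModel(sequence="".join(genomic), exons=tuple(exons),
                           strand="+", cds_start_offset=0, transcript_id="toy")


# ---------------------------------------------------------------------------
# twitch traces

@dataclass(frozen=True)
class TwitchSimSpec:
    """One simulated single twitch: linear rise to peak, exponential decay.

    The recording starts ``stim_onset`` ms before the stimulus (force sits
    at baseline), as in intact-preparation recordings, so downstream
    pre-stimulus baseline estimation has a genuine quiescent segment.
    """

    peak_force: float = 1.0       # mN (absolute peak)
    rise_time: float = 30.0       # ms
    decay_tau: float = 20.0       # ms
    baseline: float = 0.0         # mN
    duration: float = 300.0       # ms
    sample_interval: float = 1.0  # ms
    stim_onset: float = 30.0      # ms of pre-stimulus baseline
    noise_sd: float = 0.0         # mN
    seed: int = 0
    stim_frequency: float = 1.0   # Hz
    sarcomere_length_state: str = "optimal"

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.decay_tau <= 0 or self.sample_interval <= 0:
            raise ValueError("rise_time, decay_tau and sample_interval must be positive")
        if self.noise_sd < 0 or self.stim_onset < 0:
            raise ValueError("noise_sd and stim_onset must be >= 0")


def simulate_twitch_trace(spec: TwitchSimSpec, fish_id: str = "",
                          genotype: str = "") -> ForceTrace:
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.sample_interval / 2.0,
                  spec.sample_interval)
    amp = spec.peak_force - spec.baseline
    ts = t - spec.stim_onset
    rise = spec.baseline + amp * np.clip(ts, 0.0, None) / spec.rise_time
    decay = spec.baseline + amp * np.exp(-(ts - spec.rise_time) / spec.decay_tau)
    force = np.where(ts <= spec.rise_time, rise, decay)
    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return ForceTrace(time=t, force=force, stim_frequency=spec.stim_frequency,
                      sarcomere_length_state=spec.sarcomere_length_state,
                      fish_id=fish_id, genotype=genotype)


def simulate_force_frequency_traces(
    frequencies: Sequence[float] = (1, 5, 10, 20, 40, 60, 80, 100, 150, 200),
    fmax: float = 2.0, f_half: float = 25.0, noise_sd: float = 0.0,
    seed: int = 0, state: str = "optimal",
) -> list[ForceTrace]:
    """One twitch/tetanus trace per stimulation frequency.

    Peak force follows a saturating law fmax * f / (f + f_half), the usual
    shape of a force-frequency relationship.
    """
    traces = []
    root = np.random.default_rng(seed)
    for f in frequencies:
        peak = fmax * f / (f + f_half)
        sub = int(root.integers(2 ** 31))
        spec = TwitchSimSpec(peak_force=peak, noise_sd=noise_sd, seed=sub,
                             stim_frequency=float(f),
                             sarcomere_length_state=state)
        traces.append(simulate_twitch_trace(spec))
    return traces


# ---------------------------------------------------------------------------
# writers (sidecar YAML carries the generating spec = the ground truth)

def _spec_to_yaml(spec, path) -> None:
    import yaml
    from dataclasses import asdict

    d = asdict(spec)
    for key, val in list(d.items()):
        if isinstance(val, Mapping):
            d[key] = dict(val)
    with open(path, "w") as fh:
        yaml.safe_dump({"spec_type": type(spec).__name__, "truth": d}, fh,
                       sort_keys=True)


def write_profile_csv(profile: IntensityProfile, path,
                      spec: Optional[ProfileSimSpec] = None) -> None:
    import pandas as pd

    pd.DataFrame({"position_um": profile.positions,
                  "intensity_au": profile.intensities}).to_csv(path, index=False)
    if spec is not None:
        _spec_to_yaml(spec, str(path) + ".truth.yaml")


def write_counts_tsv(records: Sequence[ExonCountRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([{"exon_id": r.exon_id, "exon_length": r.exon_length,
                   "read_length": r.read_length,
                   "inclusion_reads": r.inclusion_reads,
                   "exclusion_reads": r.exclusion_reads}
                  for r in records]).to_csv(path, sep="\t", index=False)


def write_junction_tsv(locus: JunctionLocus, path) -> None:
    import pandas as pd

    rows = [{"junction_id": f"{locus.locus_id}:canonical", "kind": "canonical",
             "start": 0, "end": 0, "reads": locus.canonical_reads}]
    for label, offset, reads in locus.alternative_junctions:
        rows.append({"junction_id": label, "kind": "alternative",
                     "start": 0, "end": offset, "reads": reads})
    rows.append({"junction_id": f"{locus.locus_id}:retention",
                 "kind": "intron_retention", "start": 0, "end": 0,
                 "reads": locus.retention_reads})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trace_csv(trace: ForceTrace, path,
                    spec: Optional[TwitchSimSpec] = None) -> None:
    import pandas as pd

    pd.DataFrame({"time_ms": trace.time,
                  "force_mN": trace.force}).to_csv(path, index=False)
    if spec is not None:
        _spec_to_yaml(spec, str(path) + ".truth.yaml")
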