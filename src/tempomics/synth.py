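"""Seeded synthetic-data generators for dynamic multi-omics fixtures.

Emulates the shape of a longitudinal single-subject multi-omics profile:
a modest number of samples (default 21) collected on an uneven day grid
(default days 186-400), with per-component series that are either
periodic (sinusoids at grid-representable frequencies plus Gaussian
noise), singular spikes (a flat baseline with one extreme pulse), or pure
noise, and with values missing uniformly at random.  Every generator is
fully determined by its seed, and the planted ground truth is returned
alongside the data so classification and clustering can be scored.

Also generates small annotation fixtures (GAF-style files, two-column
mappings, identifier dictionaries) for the enrichment module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import AnnotationSet, TranslationDictionary
from .omics import MISSING, ComponentEntry, OmicsInputError, OmicsObject
from .spectral import make_frequency_grid

__all__ = [
    "PlantedTruth",
    "synth_timegrid",
    "synth_omics",
    "synth_annotations",
    "write_annotation_fixtures",
]


@dataclass
class PlantedTruth:
    """Ground truth for one synthetic dataset."""

    labels: dict  # component -> "f<k>" | "SpikeMax" | "SpikeMin" | "Null"
    frequencies: dict  # component -> planted frequency (periodic only)
    spike_times: dict  # component -> spike time (spike classes only)
    amplitude: float = 1.0
    noise_sd: float = 1.0
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    missing_rate: float = 0.0
    seed: int = 0
    mix: tuple = (0.0, 0.0, 0.0, 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "frequencies": self.frequencies,
                "spike_times": self.spike_times,
                "amplitude": self.amplitude,
                "noise_sd": self.noise_sd,
                "times": self.times.tolist(),
                "missing_rate": self.missing_rate,
                "seed": self.seed,
                "mix": list(self.mix),
            },
            indent=2,
            sort_keys=True,
        )


def synth_timegrid(
    n_points: int = 21,
    span: tuple = (186.0, 400.0),
    uneven: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Sorted distinct sampling times in ``span`` (days).

    ``uneven=True`` jitters the interior of a uniform grid by up to 40% of
    the spacing; endpoints are kept.  Times are rounded to 4 decimals so
    they survive a round trip through sample-label strings.
    """
    if n_points < 4:
        raise OmicsInputError("need at least 4 time points")
    t0, t1 = float(span[0]), float(span[1])
    if not t1 > t0:
        raise OmicsInputError(f"degenerate span {span}")
    base = np.linspace(t0, t1, n_points)
    if uneven:
        rng = np.random.default_rng(seed)
        dt = base[1] - base[0]
        jitter = rng.uniform(-0.4, 0.4, n_points) * dt
        jitter[0] = jitter[-1] = 0.0
        base = np.sort(base + jitter)
    times = np.round(base, 4)
    if len(np.unique(times)) != n_points:
        raise OmicsInputError("jittered grid produced duplicate times")
    return times


def _allocate(n: int, fractions) -> list:
    """Deterministic largest-remainder allocation of n items to classes."""
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise OmicsInputError(f"mix fractions must sum to 1, got {fr.sum()}")
    raw = fr * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def synth_omics(
    n_components: int,
    times: np.ndarray,
    mix: tuple = (0.25, 0.05, 0.05, 0.65),
    snr: float = 3.0,
    missing_rate: float = 0.2,
    noise_sd: float = 1.0,
    spike_scale: float = 8.0,
    seed: int = 0,
) -> tuple[OmicsObject, PlantedTruth]:
    """Generate a synthetic OmicsObject with planted temporal patterns.

    ``mix`` gives the fractions of (periodic, spike-max, spike-min, null)
    components; counts are allocated deterministically (largest remainder)
    and shuffled.  Periodic components are sinusoids at frequencies
    representable on the dataset's own frequency grid, with amplitude
    ``snr * noise_sd``.  Spike components are a flat noisy baseline with a
    single pulse of ``± spike_scale * noise_sd`` at a random interior
    time; the pulse must rise well above the null maximum (about 3 noise
    SD for 21 samples at the default cutoff quantile) to constitute a
    detectable singular event, hence the separate, larger default scale.
    Null components are pure Gaussian noise.  Missingness is applied
    uniformly at random, keeping at least 4 observed points per series.
    """
    if len(mix) != 4:
        raise OmicsInputError("mix must have 4 fractions")
    if snr <= 0:
        raise OmicsInputError("snr must be > 0")
    if not 0.0 <= missing_rate <= 0.9:
        raise OmicsInputError("missing_rate must be in [0, 0.9]")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    counts = _allocate(n_components, mix)
    kinds = (
        ["periodic"] * counts[0]
        + ["spike_max"] * counts[1]
        + ["spike_min"] * counts[2]
        + ["null"] * counts[3]
    )
    rng.shuffle(kinds)
    grid = make_frequency_grid(times)
    K = len(grid.frequencies)
    # stay below the pseudo-Nyquist edge so the planted peak is resolvable
    k_max = max(1, int(0.8 * K))
    amplitude = snr * noise_sd

    width = len(str(n_components))
    truth = PlantedTruth(
        labels={},
        frequencies={},
        spike_times={},
        amplitude=amplitude,
        noise_sd=noise_sd,
        times=times,
        missing_rate=missing_rate,
        seed=seed,
        mix=tuple(mix),
    )
    data = {}
    for i, kind in enumerate(kinds):
        comp = f"C{i + 1:0{width}d}"
        if kind == "periodic":
            k = int(rng.integers(1, k_max + 1))
            f = grid.frequencies[k - 1]
            phase = rng.uniform(0, 2 * np.pi)
            vec = amplitude * np.cos(2 * np.pi * f * times + phase)
            vec = vec + rng.normal(0.0, noise_sd, times.size)
            truth.labels[comp] = f"f{k}"
            truth.frequencies[comp] = float(f)
        elif kind in ("spike_max", "spike_min"):
            vec = rng.normal(0.0, noise_sd, times.size)
            j = int(rng.integers(1, times.size - 1))
            sign = 1.0 if kind == "spike_max" else -1.0
            vec[j] += sign * spike_scale * noise_sd
            truth.labels[comp] = "SpikeMax" if sign > 0 else "SpikeMin"
            truth.spike_times[comp] = float(times[j])
        else:
            vec = rng.normal(0.0, noise_sd, times.size)
            truth.labels[comp] = "Null"
        if missing_rate > 0:
            while True:
                mask = rng.random(times.size) < missing_rate
                if kind in ("spike_max", "spike_min"):
                    mask[j] = False  # the singular event itself is observed
                if (~mask).sum() >= 4:
                    break
            vec = np.where(mask, np.nan, vec)
        data[comp] = vec

    samples = {}
    for ti, t in enumerate(times):
        label = f"{t:.4f}".rstrip("0").rstrip(".")
        comps = {}
        for comp in sorted(data):
            v = data[comp][ti]
            comps[comp] = ComponentEntry(
                [MISSING if np.isnan(v) else float(v)], [truth.labels[comp]]
            )
        samples[label] = comps
    obj = OmicsObject(samples, provenance=f"synthetic (seed={seed})")
    return obj, truth


def synth_annotations(
    n_genes: int = 50,
    n_categories: int = 10,
    density: float = 0.2,
    seed: int = 0,
) -> tuple[AnnotationSet, TranslationDictionary]:
    """Random bipartite gene/category membership plus a parallel symbol ->
    accession dictionary.

    Each gene joins each category independently with probability
    ``density``; empty categories get one forced member so all categories
    are usable.  The universe is all generated genes.
    """
    if not 0.0 < density <= 1.0:
        raise OmicsInputError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    categories = {}
    descriptions = {}
    for c in range(n_categories):
        cat = f"CAT:{c + 1:04d}"
        members = {g for g in genes if rng.random() < density}
        if not members:
            members = {genes[int(rng.integers(n_genes))]}
        categories[cat] = members
        descriptions[cat] = f"synthetic category {c + 1}"
    annotations = AnnotationSet(categories, set(genes), descriptions, "custom")
    mapping = {f"SYM_{g}": [g] for g in genes}
    dictionary = TranslationDictionary("symbol", "accession", mapping)
    return annotations, dictionary


def write_annotation_fixtures(
    annotations: AnnotationSet,
    dictionary: TranslationDictionary,
    directory,
) -> dict:
    """Write GAF-style, mapping-TSV and dictionary-TSV fixture files.

    Returns the paths written.  Files are plain text and byte-for-byte
    reproducible for a fixed generator seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gaf = directory / "annotations.gaf"
    lines = ["!gaf-version: 2.2"]
    for cat in sorted(annotations.categories):
        for gene in sorted(annotations.categories[cat]):
            fields = [
                "SYNTH", gene, f"SYM_{gene}", "", cat, "SYNTH:0001", "IEA",
                "", "P", "", "", "protein", "taxon:0000", "20260101", "SYNTH",
            ]
            lines.append("\t".join(fields))
    # genes outside every category still belong to the universe
    annotated = set().union(*annotations.categories.values())
    for gene in sorted(annotations.universe - annotated):
        fields = [
            "SYNTH", gene, f"SYM_{gene}", "NOT", "CAT:0000", "SYNTH:0001",
            "IEA", "", "P", "", "", "protein", "taxon:0000", "20260101", "SYNTH",
        ]
        lines.append("\t".join(fields))
    gaf.write_text("\n".join(lines) + "\n")

    mapping_tsv = directory / "pathways.tsv"
    rows = []
    for cat in sorted(annotations.categories):
        for gene in sorted(annotations.categories[cat]):
            rows.append(f"{gene}\t{cat}\t{annotations.descriptions.get(cat, '')}")
    mapping_tsv.write_text("\n".join(rows) + "\n")

    dict_tsv = directory / "dictionary.tsv"
    rows = []
    for src in sorted(dictionary.mapping):
        for tgt in dictionary.mapping[src]:
            rows.append(f"{src}\t{tgt}")
    dict_tsv.write_text("\n".join(rows) + "\n")
    return {"gaf": gaf, "mapping": mapping_tsv, "dictionary": dict_tsv}
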