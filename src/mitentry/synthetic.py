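"""Seeded generators for synthetic inputs with the statistical structure
the analysis modules assume.

Three generators:

- :func:`generate_phospho` builds a phosphosite table with the 4 groups x
  3 replicates x 3 sixplex-batch TMT layout (each batch carries one
  replicate of every group plus two pooled reference channels), additive
  site/batch/channel effects, optional factor and interaction effects,
  and missing-not-at-random low-intensity dropout — the missingness the
  down-shifted Gaussian imputation assumes.
- :func:`generate_movie` renders nuclei as non-overlapping textured disks
  with exact label images, global photobleaching and a programmable
  intensity-variance ("condensation") ramp; NEBD is label disappearance.
  No optics/PSF simulation: the metrics under test are statistics of
  labelled regions, not detection.
- :func:`scenario_presets` ships the three population scenarios (narrow,
  broad, broad with lowered mean) used for dose-response simulations.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from mitentry.imaging import LabeledMovie
from mitentry.phospho import GROUPS, PhosphositeTable
from mitentry.population import PopulationScenario

__all__ = [
    "PhosphoSimSpec",
    "MovieSimSpec",
    "generate_phospho",
    "generate_movie",
    "scenario_presets",
]


@dataclass(frozen=True)
class PhosphoSimSpec:
    """Layout and effect sizes for a synthetic phosphosite table.

    Effects are in log2 units.  ``treatment_effect`` / ``fraction_effect``
    apply to every site with a random sign; ``interaction_effect`` applies
    only to the ``spike_fraction`` of sites drawn as true
    prolonged-prophase-specific hits.  Dropout is a logistic function of
    the true intensity with midpoint at the ``dropout_midpoint_q``
    quantile, so low-abundance values go missing preferentially.
    """

    n_sites: int = 2000
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    treatment_effect: float = 0.0
    fraction_effect: float = 0.0
    interaction_effect: float = 1.0
    spike_fraction: float = 0.05
    within_sd: float = 0.25
    batch_sd: float = 0.3
    channel_sd: float = 0.1
    dropout_midpoint_q: float = 0.15
    dropout_slope: float = 1.5
    n_replicates: int = 3
    n_reference_per_batch: int = 2
    loc_prob_low_fraction: float = 0.0  # fraction of sites given loc prob < 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spike_fraction", "dropout_midpoint_q", "loc_prob_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("within_sd", "batch_sd", "channel_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1 or self.n_replicates < 2:
            raise ValueError("need n_sites >= 1 and n_replicates >= 2")


def generate_phospho(spec: PhosphoSimSpec) -> tuple[PhosphositeTable, pd.DataFrame]:
    """Synthetic log2 TMT phosphosite table plus ground-truth labels.

    Returns ``(table, truth)`` where ``truth`` has one row per site with
    the spiked flag and the per-site signed effects actually injected.
    The spiked count is exactly ``round(spike_fraction * n_sites)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    site_ids = [f"site{i:05d}" for i in range(n)]

    residues = rng.choice(list("STY"), size=n, p=[0.65, 0.25, 0.10])
    positions = rng.integers(1, 1200, size=n)
    sites = pd.DataFrame({
        "protein": [f"PROT{i % 997:04d}" for i in range(n)],
        "gene": [f"GENE{i % 997:04d}" for i in range(n)],
        "residue": residues,
        "position": positions,
        "multiplicity": rng.integers(1, 4, size=n),
        "localization_prob": np.ones(n),
        "contaminant": np.zeros(n, dtype=bool),
        "reverse": np.zeros(n, dtype=bool),
    }, index=pd.Index(site_ids, name="site_id"))
    if spec.loc_prob_low_fraction > 0:
        n_low = int(round(spec.loc_prob_low_fraction * n))
        low = rng.choice(n, size=n_low, replace=False)
        sites.iloc[low, sites.columns.get_loc("localization_prob")] = rng.uniform(
            0.2, 0.7499, size=n_low
        )

    n_spike = int(round(spec.spike_fraction * n))
    spiked = np.zeros(n, dtype=bool)
    spiked[rng.choice(n, size=n_spike, replace=False)] = True
    sign_t = rng.choice([-1.0, 1.0], size=n)
    sign_f = rng.choice([-1.0, 1.0], size=n)
    sign_i = rng.choice([-1.0, 1.0], size=n)
    eff_treat = sign_t * spec.treatment_effect
    eff_frac = sign_f * spec.fraction_effect
    eff_inter = np.where(spiked, sign_i * spec.interaction_effect, 0.0)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)

    samples = []
    for b in range(1, spec.n_replicates + 1):
        for g, (treat, frac) in GROUPS.items():
            samples.append({
                "sample": f"{g}_r{b}", "group": g, "treatment": treat,
                "fraction": frac, "replicate": b, "batch": b,
                "is_reference": False,
            })
        for r in range(1, spec.n_reference_per_batch + 1):
            samples.append({
                "sample": f"ref{r}_b{b}", "group": "reference",
                "treatment": "pooled", "fraction": "pooled", "replicate": r,
                "batch": b, "is_reference": True,
            })
    samples = pd.DataFrame(samples).set_index("sample")

    batch_eff = {b: rng.normal(0.0, spec.batch_sd)
                 for b in range(1, spec.n_replicates + 1)}
    chan_eff = {s: rng.normal(0.0, spec.channel_sd) for s in samples.index}

    # signed half-effects so the interaction contrast equals eff_inter exactly
    def group_shift(g: str) -> np.ndarray:
        treat, frac = GROUPS[g]
        t = 0.5 if treat == "BI2536" else -0.5
        f = 0.5 if frac == "attached" else -0.5
        return eff_treat * t + eff_frac * f + eff_inter * t * f

    pooled_shift = sum(group_shift(g) for g in GROUPS) / len(GROUPS)

    values = {}
    for s, row in samples.iterrows():
        shift = pooled_shift if row["is_reference"] else group_shift(row["group"])
        noise = rng.normal(0.0, spec.within_sd, size=n)
        values[s] = baseline + shift + batch_eff[row["batch"]] + chan_eff[s] + noise
    intens = pd.DataFrame(values, index=sites.index)

    # MNAR dropout: logistic in the true intensity; slope 0 disables dropout
    if spec.dropout_slope > 0:
        flat = intens.to_numpy().copy()
        midpoint = np.quantile(flat, spec.dropout_midpoint_q)
        p_missing = 1.0 / (1.0 + np.exp(spec.dropout_slope * (flat - midpoint)))
        drop = rng.random(flat.shape) < p_missing
        flat[drop] = np.nan
        intens = pd.DataFrame(flat, index=intens.index, columns=intens.columns)

    truth = pd.DataFrame({
        "spiked": spiked,
        "interaction_effect": eff_inter,
        "treatment_effect": eff_treat,
        "fraction_effect": eff_frac,
        "baseline": baseline,
    }, index=sites.index)
    table = PhosphositeTable(sites=sites, intensities=intens, samples=samples)
    return table, truth


@dataclass(frozen=True)
class MovieSimSpec:
    """Geometry and photometry of a synthetic nucleus movie.

    ``texture_sd_schedule`` sets the per-frame SD of the Gaussian texture
    inside each nucleus — an increasing schedule emulates chromosome
    condensation.  ``nebd_frames`` maps label id -> frame at which the
    nucleus disappears (NEBD); labels absent from the map persist.
    """

    n_nuclei: int = 5
    shape: tuple[int, int] = (160, 160)
    radius_range: tuple[int, int] = (10, 14)
    base_intensity: float = 500.0
    texture_sd_schedule: tuple[float, ...] = (20.0,) * 10
    bleach_rate: float = 0.0  # per frame
    background: float = 100.0
    camera_noise_sd: float = 2.0
    frame_interval_min: float = 5.0
    nebd_frames: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.texture_sd_schedule) < 1:
            raise ValueError("schedule must cover at least one frame")
        r_max = self.radius_range[1]
        if 2 * r_max + 4 > min(self.shape):
            raise ValueError("nuclei radii do not fit the image")


def generate_movie(spec: MovieSimSpec) -> tuple[LabeledMovie, pd.DataFrame]:
    """Render the movie; returns (movie, events) with one event row per
    nucleus (label, center, radius, nebd_frame or -1)."""
    rng = np.random.default_rng(spec.seed)
    n_frames = len(spec.texture_sd_schedule)
    h, w = spec.shape
    r_lo, r_hi = spec.radius_range

    centers, radii = [], []
    attempts = 0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > 5000:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in {spec.shape}"
            )
        r = int(rng.integers(r_lo, r_hi + 1))
        cy = int(rng.integers(r + 2, h - r - 2))
        cx = int(rng.integers(r + 2, w - r - 2))
        if all(np.hypot(cy - y, cx - x) > r + rr + 3 for (y, x), rr in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)

    yy, xx = np.mgrid[:h, :w]
    base_labels = np.zeros((h, w), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        base_labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = i

    nebd = dict(spec.nebd_frames)
    labels = np.zeros((n_frames, h, w), dtype=np.int32)
    frames = np.zeros((n_frames, h, w), dtype=float)
    for t in range(n_frames):
        lab_t = base_labels.copy()
        for lid, f0 in nebd.items():
            if t >= f0:
                lab_t[lab_t == lid] = 0
        labels[t] = lab_t
        bleach = np.exp(-spec.bleach_rate * t)
        img = np.full((h, w), spec.background, dtype=float)
        inside = lab_t > 0
        texture = rng.normal(0.0, spec.texture_sd_schedule[t], size=int(inside.sum()))
        img[inside] += (spec.base_intensity + texture) * bleach
        if spec.camera_noise_sd > 0:
            img += rng.normal(0.0, spec.camera_noise_sd, size=img.shape)
        frames[t] = img

    events = pd.DataFrame({
        "label": np.arange(1, spec.n_nuclei + 1),
        "center_y": [c[0] for c in centers],
        "center_x": [c[1] for c in centers],
        "radius": radii,
        "nebd_frame": [nebd.get(i, -1) for i in range(1, spec.n_nuclei + 1)],
    })
    movie = LabeledMovie(
        frames={"dna": frames},
        labels=labels,
        background={"dna": spec.background},
        frame_interval_min=spec.frame_interval_min,
    )
    return movie, events


def scenario_presets(n_cells: int = 400, seed: int = 0) -> dict[str, PopulationScenario]:
    """The three shipped CDK2-cyclin A distributions (see data/scenarios.json).

    ``narrow`` shifts a near-step entry curve under inhibition; ``broad``
    also broadens it; ``broad_low_mean`` sits near the full-inhibition
    saddle-node so that most cells fail to enter within 24 h when PLK1 is
    completely inhibited.
    """
    text = resources.files("mitentry.data").joinpath("scenarios.json").read_text()
    raw = json.loads(text)
    return {
        name: PopulationScenario(
            name=name, mean=d["mean"], sd=d["sd"],
            n_cells=n_cells if n_cells is not None else d["n_cells"],
            distribution=d["distribution"], seed=seed,
        )
        for name, d in raw.items()
    }
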