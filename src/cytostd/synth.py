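"""Seeded generator of PBMC-like list-mode datasets with ground truth.

The generator emulates a 10-parameter stimulated-PBMC panel: forward and
side scatter, the surface markers CD123, CD11c, MHC-II and CD14, and the
intracellular cytokines IL-6, IL-12, TNF-a and IFN-a.  Events are drawn
from a Gaussian mixture on a log10 latent scale and exponentiated to
channel units, so each population is a log-normal cloud; detector
crosstalk (the configured spillover matrix) is then applied to the
fluorescence channels, and values are clipped to [0, $PnR).  Cytokine
channels are bimodal (responder / non-responder) within the
antigen-presenting populations, which gives downstream clustering some
stimulation structure to find.

The default population parameters live in ``data/populations.yaml``;
they are tuning for the example pipeline, not measured biology.  The
same seed always yields byte-identical FCS output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .compensation import SpilloverMatrix, apply_spillover, serialize_spillover_keyword
from .errors import ValidationError
from .fcs import FCSDataset, make_dataset

__all__ = [
    "POPULATION_NAMES",
    "PopulationSpec",
    "SynthConfig",
    "SynthResult",
    "default_config",
    "simulate_sample",
]

POPULATION_NAMES = (
    "monocytes", "mDC", "pDC", "B cells", "debris/dead", "novel-1", "novel-2",
)


@dataclass
class PopulationSpec:
    """One mixture component: name, weight, latent mean and covariance.

    Several specs may share a name (the responder and non-responder
    halves of a stimulated population are separate components with the
    same label).
    """

    name: str
    weight: float
    mean: np.ndarray  # length n_channels, log10 units
    covariance: np.ndarray  # (n_channels, n_channels), PD

    def __post_init__(self) -> None:
        if self.name not in POPULATION_NAMES:
            raise ValidationError(
                f"unknown population name {self.name!r}; expected one of "
                f"{', '.join(POPULATION_NAMES)}"
            )
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if self.weight < 0:
            raise ValidationError(f"population {self.name}: negative weight")
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValidationError(f"population {self.name}: covariance shape mismatch")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValidationError(
                f"population {self.name}: covariance is not positive definite"
            )


@dataclass
class SynthConfig:
    n_events: int
    seed: int
    channel_names: list[str]
    fluorescence_channels: list[str]
    populations: list[PopulationSpec]
    spillover: SpilloverMatrix
    range: float = 262144.0
    extra_keywords: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        total = sum(p.weight for p in self.populations)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"population weights sum to {total}, not 1")


@dataclass
class SynthResult:
    """Simulated dataset plus its generation ground truth."""

    dataset: FCSDataset
    labels: np.ndarray  # per-event population name
    true_events: np.ndarray  # channel units before spillover/clipping

    def __iter__(self):  # (dataset, labels) unpacking
        return iter((self.dataset, self.labels))


def _neighbour_spillover(names: list[str], adjacent: float, second: float) -> SpilloverMatrix:
    k = len(names)
    S = np.eye(k)
    for i in range(k):
        for j in range(k):
            if abs(i - j) == 1:
                S[i, j] = adjacent
            elif abs(i - j) == 2:
                S[i, j] = second
    return SpilloverMatrix(detectors=list(names), S=S)


def _load_yaml(path: str | Path | None) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    ref = resources.files("cytostd.data") / "populations.yaml"
    return yaml.safe_load(ref.read_text())


def default_config(
    n_events: int = 20000, seed: int = 42, config_file: str | Path | None = None
) -> SynthConfig:
    """Build a SynthConfig from the packaged (or a user) YAML panel file."""
    doc = _load_yaml(config_file)
    channels = list(doc["channels"])
    fluoro = list(doc["fluorescence_channels"])
    scatter_sigma = float(doc.get("scatter_sigma", 0.06))
    marker_sigma = float(doc.get("marker_sigma", 0.15))
    populations: list[PopulationSpec] = []
    for name, spec in doc["populations"].items():
        base_mean = np.array([float(spec["mean"][ch]) for ch in channels])
        sig = np.array(
            [scatter_sigma if ch in ("FSC-A", "SSC-A") else marker_sigma
             for ch in channels]
        )
        cov = np.diag(sig**2)
        resp = spec.get("responders")
        if resp:
            frac = float(resp["fraction"])
            resp_mean = base_mean.copy()
            for ch, v in resp["mean"].items():
                resp_mean[channels.index(ch)] = float(v)
            populations.append(
                PopulationSpec(name, spec["weight"] * (1 - frac), base_mean, cov)
            )
            populations.append(
                PopulationSpec(name, spec["weight"] * frac, resp_mean, cov)
            )
        else:
            populations.append(
                PopulationSpec(name, float(spec["weight"]), base_mean, cov)
            )
    sp = doc.get("spillover", {})
    spill = _neighbour_spillover(
        fluoro, float(sp.get("adjacent", 0.0)), float(sp.get("second", 0.0))
    )
    return SynthConfig(
        n_events=n_events,
        seed=seed,
        channel_names=channels,
        fluorescence_channels=fluoro,
        populations=populations,
        spillover=spill,
        range=float(doc.get("range", 262144)),
    )


def simulate_sample(config: SynthConfig) -> SynthResult:
    """Draw one sample; deterministic in ``config.seed``.

    Returns the finished dataset (spillover applied, clipped), the
    per-event population labels, and the pre-spillover channel values.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([p.weight for p in config.populations])
    counts = rng.multinomial(config.n_events, weights)
    latent_parts, label_parts = [], []
    for spec, cnt in zip(config.populations, counts):
        if cnt == 0:
            continue
        latent_parts.append(
            rng.multivariate_normal(spec.mean, spec.covariance, size=cnt,
                                    method="cholesky")
        )
        label_parts.append(np.repeat(spec.name, cnt))
    latent = np.concatenate(latent_parts)
    labels = np.concatenate(label_parts)
    order = rng.permutation(config.n_events)
    latent, labels = latent[order], labels[order]

    true_events = np.power(10.0, latent)
    observed = apply_spillover(true_events, config.spillover, config.channel_names)
    top = np.nextafter(np.float32(config.range), np.float32(0))
    observed = np.clip(observed, 0.0, float(top))

    keywords = {
        "$SPILLOVER": serialize_spillover_keyword(config.spillover),
        "$ORIGINALITY": "Original",
        "$CYT": "cytostd synthetic PBMC generator",
        **config.extra_keywords,
    }
    dataset = make_dataset(
        observed,
        channel_names=config.channel_names,
        ranges=config.range,
        extra_keywords=keywords,
    )
    return SynthResult(dataset=dataset, labels=labels, true_events=true_events)
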