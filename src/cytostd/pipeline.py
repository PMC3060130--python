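"""End-to-end example pipeline on synthetic PBMC data.

Mirrors the canonical standards workflow: raw list-mode files are
preprocessed (dead cells/debris removed by a live-cell scatter gate,
compensated, subset to the channels of interest), gated with a fixed
"manual-style" hierarchy stored as Gating-ML, clustered with a
Gaussian-mixture EM stage whose fuzzy responsibilities become a CLR
table, matched to the gated populations by Hungarian assignment, and
compared per population with precision/recall/F-measure.  Everything —
two raw FCS files, two preprocessed FCS files, two Gating-ML files, two
CLR files and the relation-bearing table of contents — is then bundled
into one ACS container.

The emulated manual gates are fixed, human-plausible regions (a scatter
rectangle for live cells, marker-pair rectangles/polygon/ellipsoid for
the populations) expressed on an asinh display scale; the coordinates
are pinned in this module because they are part of the emulated study
design.  Containers built with the same seed are byte-identical (zeroed
ZIP timestamps, deterministic clustering).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from . import acs
from .clr import CLRTable, UNCLASSIFIED, clr_from_memberships, hard_assignment, read_clr, write_clr
from .compensation import SpilloverMatrix, compensate, parse_spillover_keyword
from .errors import NumericalError, ValidationError
from .fcs import FCSDataset, make_dataset, read_fcs, write_fcs
from .gating import (
    Dimension,
    EllipsoidGate,
    GatingStrategy,
    PolygonGate,
    RectangleGate,
    evaluate_all,
    evaluate_gate,
    read_gatingml,
    write_gatingml,
)
from .synth import default_config, simulate_sample
from .transforms import Transform, apply_transform

__all__ = [
    "ComparisonResult",
    "preprocess",
    "auto_cluster",
    "match_clusters",
    "compare",
    "default_strategy",
    "build_example_acs",
    "verify_example_acs",
    "NOVEL",
]

NOVEL = "novel"

SURFACE_MARKERS = ["CD123", "CD11c", "MHC-II", "CD14"]
POPULATION_GATES = ["monocytes", "mDC", "pDC", "B cells"]

#: media types used in the example container's table of contents
MT_FCS = "application/vnd.isac.fcs"
MT_GATINGML = "application/vnd.isac.gating-ml+xml"
MT_CLR = "text/csv"


# ---------------------------------------------------------------------------
# The emulated manual gating strategy
# ---------------------------------------------------------------------------

def _scale(t: Transform, decades: float) -> float:
    """Display-space position of a log10 threshold."""
    return float(apply_transform(t, 10.0**decades))


def default_strategy(range_: float = 262144.0) -> GatingStrategy:
    """Fixed gate hierarchy for the synthetic PBMC panel.

    live (scatter rectangle)
      -> monocytes (CD14-high polygon on CD14 x MHC-II)
      -> nonmono (CD14-low rectangle)
           -> pDC (ellipsoid on CD123 x CD11c)
           -> mDC (polygon on CD123 x CD11c)
           -> B cells (rectangle on MHC-II x CD11c)

    Marker dimensions use a shared asinh display transform; the data are
    expected to be already compensated (the preprocessing step's job),
    so gate dimensions reference no compensation.
    """
    t = Transform(id="asinh", kind="fasinh", T=range_, M=4.5, A=0.0)
    s = GatingStrategy()
    s.add_transform(t)

    def dim(ch: str, lo: float = -math.inf, hi: float = math.inf) -> Dimension:
        lo_d = _scale(t, lo) if math.isfinite(lo) else -math.inf
        hi_d = _scale(t, hi) if math.isfinite(hi) else math.inf
        return Dimension(channel_name=ch, transform_ref=t.id, min=lo_d, max=hi_d)

    s.add_gate(
        RectangleGate(
            id="live",
            dims=[
                Dimension(channel_name="FSC-A", min=10**4.55, max=range_),
                Dimension(channel_name="SSC-A", min=10**4.30, max=range_),
            ],
        )
    )
    # CD14-high, MHC-II mid: a quadrilateral in display space
    cd14 = [_scale(t, d) for d in (2.7, 4.6)]
    mhc = [_scale(t, d) for d in (2.0, 4.0)]
    s.add_gate(
        PolygonGate(
            id="monocytes", parent_id="live",
            dims=[dim("CD14"), dim("MHC-II")],
            vertices=[(cd14[0], mhc[0]), (cd14[1], mhc[0]),
                      (cd14[1], mhc[1]), (cd14[0], mhc[1])],
        )
    )
    s.add_gate(
        RectangleGate(id="nonmono", parent_id="live", dims=[dim("CD14", hi=2.7)])
    )
    r = 3.5 * 0.15 / 4.5  # 3.5 sigma of a 0.15-decade marker on the 4.5-decade scale
    s.add_gate(
        EllipsoidGate(
            id="pDC", parent_id="nonmono",
            dims=[dim("CD123"), dim("CD11c")],
            mean=np.array([_scale(t, 3.6), _scale(t, 1.5)]),
            covariance=np.diag([r**2, (1.6 * r) ** 2]),
            distance_square=1.0,
        )
    )
    cd123 = [_scale(t, d) for d in (0.0, 2.2)]
    cd11c = [_scale(t, d) for d in (3.0, 4.6)]
    s.add_gate(
        PolygonGate(
            id="mDC", parent_id="nonmono",
            dims=[dim("CD123"), dim("CD11c")],
            vertices=[(cd123[0], cd11c[0]), (cd123[1], cd11c[0]),
                      (cd123[1], cd11c[1]), (cd123[0], cd11c[1])],
        )
    )
    s.add_gate(
        RectangleGate(
            id="B cells", parent_id="nonmono",
            dims=[dim("MHC-II", lo=3.3), dim("CD11c", hi=2.2)],
        )
    )
    s.validate()
    return s


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def preprocess(
    dataset: FCSDataset,
    strategy: GatingStrategy,
    spill: SpilloverMatrix | None = None,
    keep_channels: list[str] | None = None,
    live_gate: str = "live",
) -> FCSDataset:
    """Remove non-live events, compensate, and subset channels.

    ``spill`` defaults to the dataset's own $SPILLOVER keyword.  An empty
    gated result is returned as a valid 0-event dataset carrying a
    warning, not raised.
    """
    if live_gate not in strategy.gates:
        raise ValidationError(f"strategy has no live-cell gate {live_gate!r}")
    if spill is None:
        if "$SPILLOVER" not in dataset.keywords:
            raise ValidationError(
                "no spillover matrix given and the file has no $SPILLOVER"
            )
        spill = parse_spillover_keyword(dataset.keywords["$SPILLOVER"])
    keep = evaluate_gate(strategy, live_gate, dataset)
    events = compensate(dataset.events[keep], spill, dataset)
    names = dataset.channel_names
    if keep_channels is None:
        keep_channels = names
    cols = [dataset.channel_index(c) for c in keep_channels]
    out = make_dataset(
        events[:, cols],
        channel_names=list(keep_channels),
        ranges=[dataset.parameters[c].range for c in cols],
        extra_keywords={
            "PREPROCESSING": f"live-gated ({live_gate}); compensated; "
            f"subset to {len(cols)} channels",
            "$ORIGINALITY": "DataModified",
        },
    )
    if out.n_events == 0:
        out.warnings.append("live gate removed every event")
    return out


def auto_cluster(
    dataset: FCSDataset,
    k: int,
    seed: int,
    channels: list[str] | None = None,
    transform: Transform | None = None,
    n_init: int = 5,
    source_ref: str | None = None,
) -> CLRTable:
    """Gaussian-mixture EM clustering; responsibilities as a fuzzy CLR table.

    Events are mapped through ``transform`` (default: the panel's asinh
    display scale) before fitting; rows of the returned table are the
    posterior responsibilities and sum to 1.  ``n_init`` k-means++-seeded
    restarts guard against degenerate components.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if dataset.n_events < k:
        raise ValidationError(f"{dataset.n_events} events cannot form {k} clusters")
    if channels is None:
        channels = [c for c in SURFACE_MARKERS if c in dataset.channel_names] \
            or dataset.channel_names
    if transform is None:
        t_top = max(p.range for p in dataset.parameters)
        transform = Transform(id="asinh", kind="fasinh", T=t_top, M=4.5, A=0.0)
    x = np.column_stack(
        [apply_transform(transform, dataset.channel_data(c)) for c in channels]
    )
    labels = [f"cluster-{i + 1}" for i in range(k)]
    if k == 1:
        return CLRTable(labels, np.ones((dataset.n_events, 1)), source_ref=source_ref)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        random_state=int(seed) % (2**31),
        reg_covar=1e-6,
        max_iter=300,
    )
    gm.fit(x)
    if not gm.converged_:
        raise NumericalError(
            f"EM failed to converge in {n_init} restarts; try a different k"
        )
    resp = gm.predict_proba(x)
    return CLRTable(labels, resp, source_ref=source_ref)


def manual_clr(
    strategy: GatingStrategy,
    dataset: FCSDataset,
    gate_ids: list[str] | None = None,
    source_ref: str | None = None,
) -> CLRTable:
    """CLR table of 0/1 memberships for the named population gates."""
    gate_ids = gate_ids or POPULATION_GATES
    memberships, _ = evaluate_all(strategy, dataset)
    return clr_from_memberships(
        [memberships[g] for g in gate_ids], gate_ids, source_ref=source_ref
    )


def _contingency(auto_labels: np.ndarray, ref_labels: np.ndarray,
                 auto_classes: list[str], ref_classes: list[str]) -> np.ndarray:
    table = np.zeros((len(auto_classes), len(ref_classes)), dtype=np.int64)
    for i, a in enumerate(auto_classes):
        mask = auto_labels == a
        for j, r in enumerate(ref_classes):
            table[i, j] = int(np.sum(mask & (ref_labels == r)))
    return table


def match_clusters(
    clr: CLRTable, reference: CLRTable, threshold: float = 0.0
) -> dict[str, str]:
    """Map each cluster to the reference population it overlaps most.

    A maximum-weight Hungarian assignment on the cluster x population
    contingency table; clusters left without a partner (or whose best
    overlap is zero) are labelled ``novel``.
    """
    if clr.n_events != reference.n_events:
        raise ValidationError(
            f"event counts differ: {clr.n_events} vs {reference.n_events}"
        )
    auto = hard_assignment(clr, threshold=threshold)
    ref = hard_assignment(reference, threshold=max(threshold, 1e-12))
    table = _contingency(auto, ref, clr.class_labels, reference.class_labels)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {lbl: NOVEL for lbl in clr.class_labels}
    for i, j in zip(rows, cols):
        if table[i, j] > 0:
            mapping[clr.class_labels[i]] = reference.class_labels[j]
    return mapping


@dataclass
class ComparisonResult:
    """Per-population precision/recall/F plus the manual x automated table."""

    precision: dict[str, float]
    recall: dict[str, float]
    f_measure: dict[str, float]
    contingency: pd.DataFrame  # rows = manual classes, cols = automated labels

    @property
    def mean_f(self) -> float:
        return float(np.mean(list(self.f_measure.values())))


def compare(
    manual: CLRTable, automated: CLRTable, mapping: dict[str, str],
    threshold: float = 0.0,
) -> ComparisonResult:
    """Score automated populations against the manual reference.

    Hard labels are derived from both tables; automated cluster labels
    are renamed through ``mapping`` first.  F = 2PR/(P+R), 0 when both
    are 0.
    """
    if manual.n_events != automated.n_events:
        raise ValidationError("event counts differ between manual and automated")
    man = hard_assignment(manual, threshold=max(threshold, 1e-12))
    auto_raw = hard_assignment(automated, threshold=threshold)
    auto = np.array([mapping.get(a, a) for a in auto_raw], dtype=object)

    man_classes = list(manual.class_labels) + [UNCLASSIFIED]
    auto_classes = sorted(set(mapping.values()) | {UNCLASSIFIED})
    table = _contingency(man, auto, man_classes, auto_classes)
    cont = pd.DataFrame(table, index=man_classes, columns=auto_classes)

    precision, recall, fmeas = {}, {}, {}
    for pop in manual.class_labels:
        tp = int(np.sum((man == pop) & (auto == pop)))
        fp = int(np.sum((man != pop) & (auto == pop)))
        fn = int(np.sum((man == pop) & (auto != pop)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision[pop], recall[pop] = p, r
        fmeas[pop] = 2 * p * r / (p + r) if p + r else 0.0
    return ComparisonResult(precision, recall, fmeas, cont)


# ---------------------------------------------------------------------------
# The example container
# ---------------------------------------------------------------------------

def _analysis_summary(sample: str, stats: dict, comparison: ComparisonResult) -> dict:
    return {
        "sample": sample,
        "gate_counts": {g: s["count"] for g, s in stats.items()},
        "f_measure": comparison.f_measure,
        "mean_f": comparison.mean_f,
    }


def run_sample(seed: int, n_events: int = 20000, k: int = 6, sample: str = "sample1"):
    """Run the full single-sample pipeline; returns a dict of artifacts."""
    cfg = default_config(n_events=n_events, seed=seed)
    sim = simulate_sample(cfg)
    strategy = default_strategy(range_=cfg.range)
    pre = preprocess(
        sim.dataset, strategy, keep_channels=["FSC-A", "SSC-A"] + SURFACE_MARKERS
    )
    memberships, stats = evaluate_all(strategy, pre)
    man = manual_clr(strategy, pre, source_ref=f"{sample}_pre.fcs")
    clr = auto_cluster(pre, k=k, seed=seed, source_ref=f"{sample}_pre.fcs")
    mapping = match_clusters(clr, man)
    comparison = compare(man, clr, mapping)
    return {
        "config": cfg,
        "sim": sim,
        "strategy": strategy,
        "pre": pre,
        "stats": stats,
        "manual_clr": man,
        "auto_clr": clr,
        "mapping": mapping,
        "comparison": comparison,
    }


def build_example_acs(
    seed: int = 42,
    outdir: str | Path = ".",
    n_events: int = 20000,
    k: int = 6,
    filename: str = "example.acs",
) -> Path:
    """Build the two-sample example container and write it to ``outdir``.

    The container holds exactly nine members: two raw synthetic FCS
    files, two preprocessed FCS files, two Gating-ML files, two CLR
    files with the clustering results, and the table of contents whose
    relations encode the workflow (preprocessed-from,
    gating-description-of, classification-results-of).  Per-sample gate
    counts are recorded in the ToC analysis-summary roles so a reader
    can replay and verify the container without outside knowledge.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sample_seeds = [int(s) % (2**31) for s in ss.generate_state(2)]

    container = acs.ACSContainer()
    summaries = []
    for i, sseed in enumerate(sample_seeds, start=1):
        name = f"sample{i}"
        art = run_sample(sseed, n_events=n_events, k=k, sample=name)
        raw_uri = f"fcs/original/{name}.fcs"
        pre_uri = f"fcs/preprocessed/{name}_pre.fcs"
        gml_uri = f"gating/{name}.gating-ml.xml"
        clr_uri = f"clr/{name}.clr.csv"
        container.add_member(
            raw_uri, write_fcs(art["sim"].dataset), MT_FCS, role="raw FCS data file"
        )
        container.add_member(
            pre_uri, write_fcs(art["pre"]), MT_FCS, role="preprocessed FCS data file"
        )
        container.add_member(
            gml_uri, write_gatingml(art["strategy"]), MT_GATINGML,
            role="gating description",
        )
        container.add_member(
            clr_uri, write_clr(art["auto_clr"]).encode("utf-8"), MT_CLR,
            role="classification results",
        )
        container.relate(pre_uri, "preprocessed-from", raw_uri)
        container.relate(gml_uri, "gating-description-of", pre_uri)
        container.relate(clr_uri, "classification-results-of", pre_uri)
        summaries.append(_analysis_summary(name, art["stats"], art["comparison"]))

    # carry the replayable gate counts in the ToC itself (no extra member)
    for entry, summary in zip(
        [e for e in container.entries if e.media_type == MT_GATINGML], summaries
    ):
        entry.role = "gating description; analysis-summary=" + json.dumps(
            summary, sort_keys=True
        )

    out = outdir / filename
    out.write_bytes(acs.pack(container))
    return out


def verify_example_acs(path: str | Path) -> dict:
    """Replay a shipped container and check its self-consistency.

    Re-evaluates each shipped Gating-ML file on its preprocessed FCS
    file and compares the population counts with the analysis summary
    recorded in the ToC; also re-validates structure and checksums.
    Returns a report dict with ``ok`` plus per-sample details.
    """
    container = acs.unpack(path)
    findings = acs.validate(container)
    report = {
        "ok": not any(f.level == "error" for f in findings),
        "findings": [f.__dict__ for f in findings],
        "samples": [],
    }
    graph = acs.toc_to_graph(container)
    for entry in container.entries:
        if entry.media_type != MT_GATINGML:
            continue
        targets = [
            r.object_uri for r in container.relations
            if r.subject_uri == entry.uri and r.relationship == "gating-description-of"
        ]
        if not targets:
            continue
        pre = read_fcs(container.members[targets[0]])
        strategy = read_gatingml(container.members[entry.uri])
        _, stats = evaluate_all(strategy, pre)
        counts = {g: s["count"] for g, s in stats.items()}
        detail = {"gating_file": entry.uri, "data_file": targets[0],
                  "gate_counts": counts}
        marker = "analysis-summary="
        if marker in entry.role:
            recorded = json.loads(entry.role.split(marker, 1)[1])
            detail["recorded_counts"] = recorded["gate_counts"]
            detail["counts_match"] = recorded["gate_counts"] == counts
            report["ok"] = report["ok"] and detail["counts_match"]
        report["samples"].append(detail)
    report["n_members"] = len(container.members) + 1  # + the ToC itself
    report["graph_nodes"] = graph.number_of_nodes()
    return report
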