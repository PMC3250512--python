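"""End-to-end analysis runs: reports, manifests, and reproducibility.

``run_biogeography`` executes transform -> constrained tree -> multi-CV ->
size selection -> province assignment per longitude encoding scheme, plus
the Raup-Crick dendrogram; ``run_divergence`` produces the pairwise
distance and dating report.  All outputs are plain text (TSV/JSON/newick)
and fully determined by the config and seeds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import CommunityMatrix, SiteRecord, read_presence_absence, read_site_records
from .divergence import (
    RATE_PRESETS,
    date_divergence,
    pairwise_distances,
    read_fasta,
)
from .encoding import build_constraints, get_scheme
from .mrt import (
    MRTreeNode,
    TreeControl,
    assign_provinces,
    grow_tree,
    hellinger,
    multi_cv,
    prune,
    select_size,
)
from .raupcrick import agglomerate, raup_crick

logger = logging.getLogger("ventbiogeo")

__all__ = ["RunConfig", "run_biogeography", "run_divergence", "tree_to_text"]


@dataclass
class RunConfig:
    matrix_path: str
    coords_path: str
    output_dir: str
    schemes: list[str] = field(default_factory=lambda: ["greenwich_pm180"])
    folds: int = 10
    replicates: int = 100
    selection_rule: str = "most_frequent_min"
    seed: int = 0
    min_node_size: int = 2
    max_leaves: int | None = None
    linkage_method: str = "average"
    raup_crick_null: str = "equiprobable"
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for p in (self.matrix_path, self.coords_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.schemes:
            raise ValueError("at least one encoding scheme is required")
        for s in self.schemes:
            get_scheme(s)


def tree_to_text(node: MRTreeNode, site_ids: list[str], indent: int = 0) -> str:
    pad = "  " * indent
    if node.is_leaf:
        members = ", ".join(site_ids[i] for i in node.members)
        return f"{pad}leaf[{node.node_id}] n={len(node.members)} ss={node.within_ss:.6g}: {members}\n"
    out = (
        f"{pad}node[{node.node_id}] n={len(node.members)} ss={node.within_ss:.6g} "
        f"split: {node.split_var} <= {node.split_threshold:.6g}\n"
    )
    out += tree_to_text(node.left, site_ids, indent + 1)
    out += tree_to_text(node.right, site_ids, indent + 1)
    return out


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_biogeography(
    config: RunConfig,
    matrix: CommunityMatrix | None = None,
    sites: list[SiteRecord] | None = None,
) -> dict:
    """Run the full constrained-clustering analysis and write the report bundle.

    Inputs may be passed in memory (``matrix``/``sites``); otherwise they
    are read from the configured paths.  Returns a manifest dict that is
    also written to ``manifest.json``.
    """
    if matrix is None or sites is None:
        config.validate()
        matrix = read_presence_absence(config.matrix_path)
        sites = read_site_records(config.coords_path)
    site_index = {s.site_id: s for s in sites}
    missing = [sid for sid in matrix.site_ids if sid not in site_index]
    if missing:
        raise ValueError(f"sites missing coordinates: {', '.join(missing)}")
    sites = [site_index[sid] for sid in matrix.site_ids]

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    control = TreeControl(
        min_node_size=config.min_node_size, max_leaves=config.max_leaves
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        response = hellinger(matrix)

    n = matrix.n_sites
    cv_possible = config.folds <= n and n >= 2
    if not cv_possible:
        logger.warning(
            "cross-validation undefined for %d sites at v=%d; reporting the "
            "grown tree without CV",
            n,
            config.folds,
        )

    scheme_reports = {}
    for scheme_name in config.schemes:
        scheme = get_scheme(scheme_name)
        sdir = outdir / scheme.name
        sdir.mkdir(exist_ok=True)
        constraints = build_constraints(sites, scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tree = grow_tree(response, constraints, control)
        sequence = prune(tree)

        selected: dict[str, int]
        if cv_possible and sequence.root_ss > 0:
            summary = multi_cv(
                response,
                constraints,
                replicates=config.replicates,
                folds=config.folds,
                seed=config.seed,
                control=control,
            )
            summary.to_frame().to_csv(sdir / "xerror.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "size": list(summary.frequencies),
                    "frequency": list(summary.frequencies.values()),
                }
            ).to_csv(sdir / "size_frequencies.tsv", sep="\t", index=False)
            selected = {
                r: select_size(summary, r) for r in ("most_frequent_min", "one_se")
            }
        else:
            summary = None
            selected = {
                "most_frequent_min": sequence.entries[0].n_leaves,
                "one_se": sequence.entries[-1].n_leaves,
            }
        size = selected[config.selection_rule]
        assignment = assign_provinces(sequence, size, response.site_ids)
        pd.DataFrame(
            {
                "site_id": list(assignment),
                "province": list(assignment.values()),
                "latitude_deg": [site_index[s].latitude_deg for s in assignment],
                "longitude_deg": [site_index[s].longitude_deg for s in assignment],
            }
        ).to_csv(sdir / "provinces.tsv", sep="\t", index=False)
        (sdir / "tree.txt").write_text(
            tree_to_text(tree, response.site_ids), encoding="utf-8"
        )
        _write_json(tree.to_dict(response.site_ids), sdir / "tree.json")
        _write_json(
            {
                "scheme": scheme.name,
                "selected_size": selected,
                "selection_rule": config.selection_rule,
                "achievable_sizes": sequence.sizes,
            },
            sdir / "selection.json",
        )
        if config.plots and summary is not None:
            _plot_size_selection(summary, sdir / "size_selection.png")
        scheme_reports[scheme.name] = {
            "selected_size": selected,
            "n_provinces": size,
            "achievable_sizes": sequence.sizes,
        }

    if len(config.schemes) > 1:
        rows = [
            {"scheme": name, **{f"size_{r}": v for r, v in rep["selected_size"].items()}}
            for name, rep in scheme_reports.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "scheme_comparison.tsv", sep="\t", index=False)

    # unconstrained probabilistic clustering
    rc = raup_crick(matrix, null_model=config.raup_crick_null, seed=config.seed)
    rc.to_frame().to_csv(outdir / "raup_crick.tsv", sep="\t", index_label="site_id")
    if n >= 2:
        dendro = agglomerate(rc, method=config.linkage_method)
        (outdir / "dendrogram.nwk").write_text(
            dendro.to_newick() + "\n", encoding="utf-8"
        )

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_sites": n,
        "n_species": matrix.n_species,
        "binary": matrix.binary,
        "schemes": scheme_reports,
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _plot_size_selection(summary, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7))
    ax1.bar(list(summary.frequencies), list(summary.frequencies.values()))
    ax1.set_xlabel("optimal tree size")
    ax1.set_ylabel("frequency")
    sizes = summary.sizes
    ax2.errorbar(sizes, summary.xerror_mean, yerr=summary.xerror_se, fmt="o-")
    i_min = int(summary.xerror_mean.argmin())
    ax2.axhline(summary.xerror_mean[i_min] + summary.xerror_se[i_min], ls="--", c="grey")
    ax2.set_xlabel("tree size")
    ax2.set_ylabel("cross-validated relative error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_divergence(
    alignment_path: str | Path,
    rate_percent_per_my: float = RATE_PRESETS["anomuran_16s"],
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Pairwise TN93 distances (percent) with rate-based divergence dates."""
    seqs = read_fasta(alignment_path)
    if len(seqs.ids) < 2:
        raise ValueError("need at least 2 sequences")
    rows = []
    for id_a, id_b, dist in pairwise_distances(seqs):
        if dist is None:
            rows.append(
                {
                    "seq_a": id_a,
                    "seq_b": id_b,
                    "distance_percent": float("nan"),
                    "time_my": float("nan"),
                    "note": "saturated",
                }
            )
        else:
            est = date_divergence(dist.percent, rate_percent_per_my)
            rows.append(
                {
                    "seq_a": id_a,
                    "seq_b": id_b,
                    "distance_percent": round(dist.percent, 6),
                    "time_my": round(est.time_my, 6),
                    "note": "",
                }
            )
    df = pd.DataFrame(rows)
    if output_path is not None:
        df.to_csv(output_path, sep="\t", index=False)
    return df
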