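"""End-to-end orchestration: simulate/read -> beta -> realms -> chronology
-> drivers -> node divergence, with a reproducibility manifest.

Every run writes its artifacts plus ``manifest.json`` recording input
hashes, the configuration echo, the master seed and output hashes;
identical configuration and seed give identical manifests, which is what
makes sensitivity reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import io as fio
from .beta import pairwise_beta
from .chronology import chronology_run
from .containers import Partition
from .drivers import CostParams, driver_series, isolation_series
from .errors import InvalidParameterError
from .nodes import (
    clade_contribution,
    high_divergence_nodes,
    node_occupancy,
    sos_scores,
)
from .regionalize import (
    fuzzy_membership,
    nmds,
    regionalize,
    silhouette_widths,
)

logger = logging.getLogger("florealm")

__all__ = ["RunConfig", "run_pipeline", "sensitivity_runs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    tree_path: str | None = None
    occurrences_path: str | None = None
    gsu_table_path: str | None = None
    climate_path: str | None = None
    paleo_dir: str | None = None
    mode: str = "phylogenetic"  # taxonomic | phylogenetic
    pbeta_realm: float = 0.80
    pbeta_subrealm: float = 0.95
    pbeta_selection: float = 0.99
    linkage: str = "average"  # or 'auto'
    times: list[float] = field(default_factory=lambda: [float(t) for t in range(0, 170, 10)])
    k_ocean: float = 10.0
    k_elev: float = 1.0
    fuzziness: float = 1.5
    n_rand: int = 200
    gnd_threshold: float = 0.65
    seed: int = 0
    run_chronology: bool = True
    run_nodes: bool = True
    run_drivers: bool = False
    driver_realm_pair: tuple[int, int] | None = None

    def __post_init__(self):
        if self.mode not in ("taxonomic", "phylogenetic"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not 0 < self.pbeta_realm < self.pbeta_subrealm <= 1:
            raise InvalidParameterError(
                "need 0 < realm threshold < sub-realm threshold <= 1"
            )
        if self.mode == "phylogenetic" and self.tree_path is None:
            raise InvalidParameterError("phylogenetic mode needs a tree")
        if (self.run_chronology or self.run_nodes) and self.tree_path is None:
            raise InvalidParameterError(
                "chronology and node divergence need a tree; disable them "
                "or supply tree_path"
            )
        if self.run_drivers and (
            self.climate_path is None or self.paleo_dir is None
        ):
            raise InvalidParameterError(
                "driver analysis needs climate_path and paleo_dir"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "driver_realm_pair" in payload and payload["driver_realm_pair"]:
            payload["driver_realm_pair"] = tuple(payload["driver_realm_pair"])
        try:
            return cls(**payload)
        except TypeError as exc:
            raise InvalidParameterError(f"bad config {path}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``<out>/manifest.json``). Any
    stage failure propagates with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for name in (
        "tree_path",
        "occurrences_path",
        "gsu_table_path",
        "climate_path",
    ):
        value = getattr(config, name)
        if value:
            inputs[name] = _sha256(Path(value))

    stage = "read"
    try:
        tree = fio.read_tree(config.tree_path) if config.tree_path else None
        occ = fio.read_occurrences(config.occurrences_path, tree=tree)
        gsu_table = (
            fio.read_gsu_table(config.gsu_table_path)
            if config.gsu_table_path
            else None
        )

        stage = "beta"
        beta = pairwise_beta(occ, tree=tree, mode=config.mode)
        fio.write_beta_matrix(beta, out / "beta.csv")

        stage = "regionalize"
        reg = regionalize(
            beta,
            pbeta_realm=config.pbeta_realm,
            pbeta_subrealm=config.pbeta_subrealm,
            linkage_method=config.linkage,
            selection_threshold=config.pbeta_selection,
        )
        sil = silhouette_widths(reg.realms, beta) if reg.realms.k >= 2 else None
        if gsu_table is not None:
            fio.write_regionalization(
                reg.realms,
                reg.subrealms,
                gsu_table,
                out / "regionalization.csv",
                out / "regionalization.geojson",
                silhouette=sil,
            )
        if reg.linkage_evaluation is not None:
            reg.linkage_evaluation.to_csv(
                out / "linkage_evaluation.csv", index=False
            )
        coords, stress = nmds(beta, seed=config.seed, n_starts=16)
        coords.to_csv(out / "nmds.csv")
        if reg.realms.k >= 2:
            fuzzy_membership(
                beta, reg.realms.k, fuzziness=config.fuzziness,
                seed=config.seed,
            ).frame.to_csv(out / "membership.csv")

        slices = None
        if config.run_chronology and tree is not None:
            stage = "chronology"
            slices = chronology_run(
                tree,
                occ,
                config.times,
                pbeta=config.pbeta_realm,
                linkage_method=(
                    config.linkage if config.linkage != "auto" else "average"
                ),
                seed=config.seed,
            )
            rows = []
            for ts in slices:
                for gsu, lab in sorted(ts.partition.labels.items()):
                    rows.append(
                        {
                            "time": ts.t,
                            "gsu_id": gsu,
                            "cluster": lab,
                            "matched_label": ts.label_map.get(lab, ""),
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "chronology.csv", index=False)

        if config.run_drivers:
            stage = "drivers"
            surfaces = fio.read_cost_surfaces(config.paleo_dir)
            iso = isolation_series(
                surfaces,
                gsu_table,
                CostParams(k_ocean=config.k_ocean, k_elev=config.k_elev),
            )
            clim_series = [
                fio.read_climate(p, time=s.time)
                for s, p in zip(
                    surfaces,
                    sorted(Path(config.paleo_dir).glob("paleoclim_*.csv")),
                )
            ]
            pair = config.driver_realm_pair or (1, 2)
            ds = driver_series(beta, reg.realms, pair, iso, clim_series)
            ds.steps.to_csv(out / "driver_steps.csv", index=False)
            ds.bins.to_csv(out / "driver_bins.csv", index=False)

        if config.run_nodes and tree is not None:
            stage = "nodes"
            nodes_table = high_divergence_nodes(
                tree, occ, threshold=config.gnd_threshold
            )
            nodes_table.to_csv(out / "node_scores.csv", index=False)
            contrib_rows = []
            realms = sorted(set(reg.realms.labels.values()))
            for _, row in nodes_table.iterrows():
                occupancy = node_occupancy(tree, occ, row["node_id"])
                sos = sos_scores(
                    occupancy,
                    n_rand=config.n_rand,
                    seed=config.seed + hash(row["node_id"]) % 10000,
                )
                for a in range(len(realms)):
                    for b in range(a + 1, len(realms)):
                        try:
                            r2 = clade_contribution(
                                sos, reg.realms, (realms[a], realms[b])
                            )
                        except Exception:
                            continue
                        contrib_rows.append(
                            {
                                "node_id": row["node_id"],
                                "realm_p": realms[a],
                                "realm_q": realms[b],
                                "anova_r2": r2,
                            }
                        )
            pd.DataFrame(
                contrib_rows,
                columns=["node_id", "realm_p", "realm_q", "anova_r2"],
            ).to_csv(out / "clade_contributions.csv", index=False)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    outputs = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        and p.name != "manifest.json"
    }
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def sensitivity_runs(
    occ_path,
    tree_paths: list,
    pbeta_realm: float = 0.80,
    linkage_method: str = "average",
    mode: str = "phylogenetic",
) -> pd.DataFrame:
    """Regionalize under alternative trees and cross-compare realms.

    Each tree is intersected with the occurrence table (shared genera);
    the result is the adjusted-Rand-index matrix between the realm
    partitions, with tree file names as labels.
    """
    if len(tree_paths) < 2:
        raise InvalidParameterError("need at least 2 trees to compare")
    partitions: list[tuple[str, Partition]] = []
    for path in tree_paths:
        tree = fio.read_tree(path)
        occ = fio.read_occurrences(occ_path, tree=tree)
        beta = pairwise_beta(occ, tree=tree, mode=mode)
        reg = regionalize(
            beta, pbeta_realm=pbeta_realm, linkage_method=linkage_method
        )
        partitions.append((Path(path).name, reg.realms))
    names = [n for n, _ in partitions]
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, (_, pi) in enumerate(partitions):
        for j, (_, pj) in enumerate(partitions):
            shared = sorted(set(pi.labels) & set(pj.labels))
            if not shared:
                raise InvalidParameterError(
                    "partitions share no GSUs; occurrence/tree overlap empty"
                )
            table.iloc[i, j] = adjusted_rand_score(
                pi.label_vector(shared), pj.label_vector(shared)
            )
    return table
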