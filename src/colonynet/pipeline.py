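"""End-to-end analysis pipeline.

Runs the full chain — logs -> sociomatrices -> hierarchy + network metrics ->
communities (bootstrap consensus) -> association tests -> spatial analyses —
from a single configuration, writing every artifact and a machine-readable
JSON report. A single master seed deterministically derives independent
per-stage sub-seeds, so the randomness of one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import community as comm
from . import hierarchy as hier
from . import io
from . import network as net
from . import spatial as spat
from .datamodel import (
    CensusLog,
    EventLog,
    ValidationError,
    binarize,
    build_frequency_matrix,
    symmetrize,
)
from .simulate import SimConfig, simulate_colony

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("hierarchy", "network", "communities", "association", "spatial")


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for one full analysis run.

    Exactly one of (``events_path``,) or ``simulation`` must be provided;
    ``census_path`` accompanies ``events_path`` when census analyses are
    wanted.
    """

    events_path: str | None = None
    census_path: str | None = None
    simulation: SimConfig | None = None
    out_dir: str = "colonynet_out"
    seed: int = 0
    n_rand: int = 10000
    n_rand_transitivity: int = 1000
    n_boot: int = 1000
    n_random_graphs: int = 5000
    extreme_replicates: int = 20
    n_perm_mantel: int = 1000
    assign_threshold: float = 0.5
    isi_restarts: int = 20
    nmds_starts: int = 20

    def validate(self) -> None:
        has_files = self.events_path is not None
        if has_files == (self.simulation is not None):
            raise ValidationError(
                "config must supply exactly one of events_path or simulation"
            )


def _subseeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order and return the report dict.

    Artifacts (matrices as TSV, results as JSON) are written under
    ``config.out_dir``. Stages whose preconditions fail (e.g. N < 3) are
    reported as ``{"not_computed": reason}`` rather than aborting the others.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _subseeds(config.seed, 8)

    # --- inputs
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation)
        ds = simulate_colony(sim_cfg)
        events, census = ds.events, ds.census
        io.write_event_log(events, out / "events.csv")
        io.write_census_log(census, out / "census.csv")
        io.write_report(
            {"true_communities": ds.true_communities, "true_order": ds.true_order},
            out / "truth.json",
        )
    else:
        events = io.read_event_log(config.events_path)
        census = (
            io.read_census_log(config.census_path, roster=events.roster)
            if config.census_path
            else None
        )

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "n_events": events.n_events,
            "n_individuals": events.n_individuals,
            "config": {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        }
    }

    freq = build_frequency_matrix(events)
    binary = binarize(freq)
    sym = symmetrize(freq)
    io.write_matrix(freq, out / "frequency_matrix.tsv")
    io.write_matrix(binary, out / "binary_matrix.tsv")

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except ValidationError as err:
            log.warning("stage %s not computed: %s", name, err)
            result = {"not_computed": str(err)}
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        report[name] = result
        return result

    # --- hierarchy
    def _hierarchy():
        hs = hier.hierarchy_summary(freq, n_rand=config.n_rand, seed=rngs[0])
        tri = hier.triangle_transitivity(
            binary, n_rand=config.n_rand_transitivity, seed=rngs[1]
        )
        ranking = hier.isi_rank(
            binary, n_restarts=config.isi_restarts, seed=rngs[2]
        )
        pd.Series(ranking.ranks, name="isi_rank").rename_axis("id").to_csv(
            out / "ranks.tsv", sep="\t"
        )
        return {
            "h_prime": hs.h_prime,
            "h_prime_p": hs.h_prime_p,
            "steepness": hs.steepness,
            "steepness_p": hs.steepness_p,
            "directional_consistency": hs.dc,
            "directional_consistency_p": hs.dc_p,
            "n_rand": config.n_rand,
            "transitivity": dataclasses.asdict(tri),
            "isi": dataclasses.asdict(ranking),
        }

    hierarchy_result = stage("hierarchy", _hierarchy)

    # --- network
    def _network():
        summ = net.network_summary(
            binary,
            n_rand=config.n_rand,
            n_random_graphs=config.n_random_graphs,
            replicates=config.extreme_replicates,
            seed=rngs[3],
        )
        isi_order = (
            hierarchy_result.get("isi", {}).get("ordering")
            if isinstance(hierarchy_result, dict)
            else None
        )
        nm = net.node_metrics(binary, isi_order=isi_order)
        nm.rename_axis("id").to_csv(out / "node_metrics.tsv", sep="\t")
        corr = net.correlate_node_measures(nm)
        return {
            "summary": dataclasses.asdict(summ),
            "correlations": corr.to_dict(orient="records"),
        }

    stage("network", _network)

    # --- communities
    def _communities():
        com = comm.bootstrap_comembership(events, n_boot=config.n_boot, seed=rngs[4])
        io.write_matrix(com, out / "comembership.tsv")
        consensus = comm.consensus_communities(
            com, assign_threshold=config.assign_threshold
        )
        single = comm.girvan_newman(sym)
        return {
            "consensus": {
                "membership": consensus.membership,
                "sizes": consensus.sizes,
                "q_max": consensus.q_max,
            },
            "single_run": {
                "membership": single.membership,
                "sizes": single.sizes,
                "q_max": single.q_max,
            },
            "n_boot": config.n_boot,
            "_comembership": com,
            "_consensus_obj": consensus,
        }

    communities_result = stage("communities", _communities)

    # --- association
    def _association():
        if census is None:
            raise ValidationError("no census log supplied")
        hwi = assoc.hwi_matrix(census)
        io.write_matrix(hwi, out / "hwi.tsv")
        result = {"n_dyads": int(np.isfinite(hwi.to_numpy()).sum() // 2)}
        if "_comembership" in communities_result:
            com = communities_result["_comembership"]
            r, p = assoc.mantel_test(
                hwi, com, n_perm=config.n_perm_mantel, seed=rngs[5]
            )
            result["mantel_r"] = r
            result["mantel_p"] = p
            try:
                result["within_between"] = assoc.within_between_test(
                    hwi,
                    communities_result["_consensus_obj"],
                    n_rand=config.n_rand,
                    seed=rngs[6],
                )
            except ValidationError as err:
                result["within_between"] = {"not_computed": str(err)}
        return result

    stage("association", _association)

    # --- spatial
    def _spatial():
        usage = spat.location_usage(events)
        usage.given.rename_axis("id").to_csv(out / "usage_given.tsv", sep="\t")
        usage.received.rename_axis("id").to_csv(out / "usage_received.tsv", sep="\t")
        even = {}
        rng_even = rngs[7]
        for ind in usage.given.index:
            g = usage.given.loc[ind].to_numpy()
            r = usage.received.loc[ind].to_numpy()
            even[ind] = {
                "J_given": spat.shannon_evenness(g) if g.sum() else None,
                "J_received": spat.shannon_evenness(r) if r.sum() else None,
                "p_given": (
                    spat.evenness_significance(g, n_rand=config.n_rand, seed=rng_even)
                    if g.sum()
                    else None
                ),
                "p_received": (
                    spat.evenness_significance(r, n_rand=config.n_rand, seed=rng_even)
                    if r.sum()
                    else None
                ),
            }
        dist = spat.usage_distance(usage)
        ord_res = spat.nmds(dist, n_starts=config.nmds_starts, seed=config.seed)
        ord_res.coords.rename_axis("id").to_csv(out / "ordination.tsv", sep="\t")
        return {
            "evenness": even,
            "nmds_stress": ord_res.stress,
            "nmds_converged": ord_res.converged,
        }

    stage("spatial", _spatial)

    # strip non-serializable intermediates before writing
    if isinstance(report.get("communities"), dict):
        report["communities"] = {
            k: v for k, v in report["communities"].items() if not k.startswith("_")
        }
    io.write_report(report, out / "report.json")
    return report
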