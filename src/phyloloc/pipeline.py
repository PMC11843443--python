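"""Pipeline orchestration: simulate -> age -> enrich -> pairs -> diverge ->
ppi -> paralogs, driven by one flat configuration, with a run manifest.

Every stage reads files written by earlier stages (or supplied externally),
writes its outputs into the run directory and records row counts and output
hashes in ``manifest.json``.  All randomness flows from the single master
seed via named substreams, so a rerun with an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import (
    age_dating,
    divergence,
    localization,
    pair_stats,
    paralog_localization,
    ppi_compartments,
    synthetic_data,
    tables_io,
)
from .vocab import age_class

log = logging.getLogger(__name__)

STAGES = ("simulate", "age", "enrich", "pairs", "diverge", "ppi", "paralogs")


@dataclass
class RunConfig:
    """All paths, thresholds and the master seed for one pipeline run.

    Threshold defaults are the analysis constants: localization call 0.5,
    interaction score cutoff 700, masked-exon cutoff 0.70, clustering
    identity 0.5 with word length 3, minimum 40 clusters per compartment,
    100 co-localization iterations, 50 interaction simulations of 50,000
    sampled pairs each.
    """

    outdir: str = "phyloloc_run"
    seed: int = 0
    # input paths (defaults point into outdir, where `simulate` writes them)
    presence_path: str = ""
    secondary_presence_path: str = ""
    localization_path: str = ""
    links_path: str = ""
    pathways_path: str = ""
    paralogs_path: str = ""
    fasta_path: str = ""
    gtf_path: str = ""
    # thresholds
    localization_threshold: float = 0.5
    score_cutoff: float = 700.0
    masked_exon_cutoff: float = 0.70
    cluster_identity: float = 0.5
    cluster_word_length: int = 3
    min_clusters_per_compartment: int = 40
    coloc_iterations: int = 100
    coloc_strategy: str = "A"
    ppi_sims: int = 50
    ppi_sample: int = 50_000
    # simulation size knobs (forwarded to SimulationParams)
    n_genes: int = 2000
    n_edges: int = 10_000

    def resolved_path(self, key: str, default_name: str) -> Path:
        value = getattr(self, key)
        if value:
            return Path(value)
        return Path(self.outdir) / default_name

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)


_INPUT_DEFAULTS = {
    "presence_path": "presence.tsv",
    "secondary_presence_path": "secondary_presence.tsv",
    "localization_path": "localization.csv",
    "links_path": "physical_links.txt",
    "pathways_path": "pathways.tsv",
    "paralogs_path": "paralogs.tsv",
    "fasta_path": "proteins.fa",
    "gtf_path": "annotation.gtf",
}

_STAGE_INPUTS = {
    "simulate": (),
    "age": ("presence_path",),
    "enrich": ("localization_path",),
    "pairs": ("localization_path", "pathways_path"),
    "diverge": ("fasta_path", "localization_path"),
    "ppi": ("links_path", "localization_path"),
    "paralogs": ("paralogs_path", "localization_path", "fasta_path"),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.manifest: dict = {
            "config": asdict(config),
            "seed": config.seed,
            "stages": {},
        }

    # -- helpers -------------------------------------------------------------

    def _input(self, key: str) -> Path:
        return self.config.resolved_path(key, _INPUT_DEFAULTS[key])

    def _age_table_path(self) -> Path:
        return self.outdir / "gene_ages.tsv"

    def _load_ages(self) -> dict[str, str]:
        path = self._age_table_path()
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found: run the 'age' stage first (or supply it)"
            )
        return {r.gene_id: r.branch for r in tables_io.read_age_table(path)}

    def _load_called_sets(self) -> dict[str, frozenset[str]]:
        table = tables_io.read_localization_table(self._input("localization_path"))
        return localization.called_sets_from_table(
            table, self.config.localization_threshold
        )

    def _record(self, stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "hashes": {k: _sha256(p) for k, p in outputs.items()},
            "counts": counts,
        }

    # -- stages --------------------------------------------------------------

    def run_simulate(self) -> None:
        params = synthetic_data.SimulationParams(
            n_genes=self.config.n_genes,
            n_edges=self.config.n_edges,
            seed=self.config.seed,
        )
        dataset = synthetic_data.simulate(params)
        paths = dataset.write_all(self.outdir)
        self._record(
            "simulate",
            paths,
            {
                "genes": len(dataset.truth.true_branch),
                "edges": len(dataset.links),
                "paralog_pairs": len(dataset.paralog_pairs),
            },
        )

    def run_age(self) -> None:
        presence = tables_io.read_presence_matrix(self._input("presence_path"))
        clade_map = age_dating.default_clade_map()
        ages = age_dating.assign_ages(presence, clade_map).to_dict()
        moved = 0
        sec_path = self._input("secondary_presence_path")
        if sec_path.exists():
            sec = pd.read_csv(sec_path, sep="\t", index_col=0)["present"].astype(bool)
            ages, moved = age_dating.apply_loss_correction(
                ages, sec.to_dict(), "br0", "br-1"
            )
        records = age_dating.records_from_ages(ages)
        out = self._age_table_path()
        tables_io.write_age_table(records, out)
        counts = age_dating.branch_counts(records)
        counts["loss_corrected"] = moved
        self._record("age", {"age_table": out}, counts)

    def run_enrich(self) -> None:
        ages = self._load_ages()
        called = self._load_called_sets()
        out_paths = {}
        counts = {}
        for level in ("compartment9", "level3"):
            table = localization.enrichment(ages, called, level=level)
            path = self.outdir / f"enrichment_{level}.tsv"
            table.to_csv(path, sep="\t", index=False)
            out_paths[f"enrichment_{level}"] = path
            counts[f"rows_{level}"] = len(table)
            counts["unlocalized"] = table.attrs["n_unlocalized"]
        breadth_rows = []
        for k in (2, 3, 4):
            breadth_rows.append(localization.breadth_by_age(called, ages, k))
        breadth = pd.concat(breadth_rows, ignore_index=True)
        bpath = self.outdir / "breadth.tsv"
        breadth.to_csv(bpath, sep="\t", index=False)
        out_paths["breadth"] = bpath
        self._record("enrich", out_paths, counts)

    def run_pairs(self) -> None:
        ages = self._load_ages()
        called = self._load_called_sets()
        single = {
            p: next(iter(s)) for p, s in called.items() if len(s) == 1
        }
        results = pair_stats.colocalization_excess(
            ages, single,
            strategy=self.config.coloc_strategy,
            n_iter=self.config.coloc_iterations,
            seed=self.config.seed,
        )
        table = pair_stats.colocalization_table(results)
        cpath = self.outdir / "colocalization.tsv"
        table.to_csv(cpath, sep="\t", index=False)
        usable = table[~table["skipped"]]
        reg_path = self.outdir / "colocalization_regression.tsv"
        try:
            reg = pair_stats.excess_vs_branch_regression(
                usable["mean_excess_pct"].tolist()
            )
        except ValueError:
            reg = None
        with open(reg_path, "w") as fh:
            fh.write("r\tp_value\tslope\tintercept\tflagged\n")
            if reg is None:
                fh.write("NA\tNA\tNA\tNA\tTrue\n")
            else:
                fh.write(f"{reg.r}\t{reg.p_value}\t{reg.slope}\t{reg.intercept}\t{reg.flagged}\n")
        pathways = tables_io.read_pathways(self._input("pathways_path"))
        cof = pair_stats.cofunction_expectation(pathways, ages)
        fpath = self.outdir / "cofunction.tsv"
        pair_stats.cofunction_table(cof).to_csv(fpath, sep="\t", index=False)
        self._record(
            "pairs",
            {"colocalization": cpath, "regression": reg_path, "cofunction": fpath},
            {"branches": len(table), "single_localized": len(single)},
        )

    def run_diverge(self) -> None:
        sequences = tables_io.read_fasta(self._input("fasta_path"))
        called = self._load_called_sets()
        ages = self._load_ages()
        clusters = divergence.greedy_cluster(
            sequences,
            threshold=self.config.cluster_identity,
            word_length=self.config.cluster_word_length,
        )
        filtered = divergence.filter_clusters(
            clusters, called,
            min_clusters_per_compartment=self.config.min_clusters_per_compartment,
        )
        cds = divergence.compute_cluster_divergences(
            filtered, sequences,
            {g: age_class(b) for g, b in ages.items()},
        )
        summary, pvals = divergence.compare_compartment_divergence(cds)
        cpath = self.outdir / "clusters.tsv"
        pd.DataFrame(
            [
                {
                    "cluster_id": cd.cluster_id,
                    "compartment": cd.compartment,
                    "n_members": len(cd.members),
                    "members": ";".join(cd.members),
                    "d_value": cd.d_value,
                }
                for cd in cds
            ]
        ).to_csv(cpath, sep="\t", index=False)
        spath = self.outdir / "divergence_summary.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        ppath = self.outdir / "divergence_pvalues.tsv"
        pvals.to_csv(ppath, sep="\t")
        self._record(
            "diverge",
            {"clusters": cpath, "summary": spath, "pvalues": ppath},
            {"clusters_total": len(clusters), "clusters_retained": len(cds)},
        )

    def run_ppi(self) -> None:
        graph = ppi_compartments.load_links(
            self._input("links_path"), self.config.score_cutoff
        )
        called = self._load_called_sets()
        nodes = [n for n in graph.nodes if called.get(n)]
        sub = graph.subgraph(nodes).copy()
        matrix = ppi_compartments.density_matrix(sub, called)
        mpath = self.outdir / "density_matrix.tsv"
        matrix.to_csv(mpath, sep="\t")
        sim = ppi_compartments.wc_bc_simulation(
            sub, called,
            n_sims=self.config.ppi_sims,
            sample_size=self.config.ppi_sample,
            seed=self.config.seed,
        )
        spath = self.outdir / "wc_bc_simulation.tsv"
        pd.DataFrame(
            {
                "sim": range(sim.n_sims),
                "wc_count": sim.wc_counts,
                "bc_count": sim.bc_counts,
                "wc_per_gene": sim.wc_per_gene,
                "bc_per_gene": sim.bc_per_gene,
            }
        ).to_csv(spath, sep="\t", index=False)
        with open(self.outdir / "wc_bc_test.tsv", "w") as fh:
            fh.write("statistic\tp_value\n")
            fh.write(f"{sim.statistic}\t{sim.p_value}\n")
        self._record(
            "ppi",
            {"density_matrix": mpath, "simulation": spath,
             "test": self.outdir / "wc_bc_test.tsv"},
            {"edges": sub.number_of_edges(), "nodes": sub.number_of_nodes()},
        )

    def run_paralogs(self) -> None:
        pairs = tables_io.read_paralog_table(self._input("paralogs_path"))
        ages = self._load_ages()
        called = self._load_called_sets()
        sequences = tables_io.read_fasta(self._input("fasta_path"))
        classified, attrition = paralog_localization.classify_pairs(pairs, ages, called)
        ptable = paralog_localization.pairs_table(classified)
        ppath = self.outdir / "classified_pairs.tsv"
        ptable.to_csv(ppath, sep="\t", index=False)
        spectrum = paralog_localization.pattern_spectrum(classified)
        spath = self.outdir / "pattern_spectrum.tsv"
        spectrum.to_csv(spath, sep="\t", index=False)
        result = paralog_localization.k_vs_nonk_comparison(classified, sequences)
        kpath = self.outdir / "k_vs_nonk.tsv"
        with open(kpath, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"similarity_p_one_sided\t{result.similarity_p}\n")
            fh.write(f"position_p_two_sided\t{result.position_p}\n")
            fh.write(f"k_bins\t{result.k_bins}\n")
            fh.write(f"nonk_bins\t{result.nonk_bins}\n")
        self._record(
            "paralogs",
            {"pairs": ppath, "spectrum": spath, "k_vs_nonk": kpath},
            attrition,
        )

    # -- driver --------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        ordered = [s for s in STAGES if s in stages]
        # pre-flight: every input needed by a requested stage must exist or
        # be produced by an earlier requested stage
        will_simulate = "simulate" in ordered
        for stage in ordered:
            for key in _STAGE_INPUTS[stage]:
                path = self._input(key)
                if not path.exists() and not will_simulate:
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {key} = {path}, which does not exist"
                    )
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in ordered:
            log.info("running stage %s", stage)
            getattr(self, f"run_{stage}")()
        mpath = self.outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.manifest


def run(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    return Pipeline(config).run(stages)
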