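"""Tabular and JSON input/output plus seeded fixture generation.

File conventions
----------------
* individual-size tables: TSV/CSV with columns ``site_id, individual_id,
  size`` (optional ``size_units``), one row per individual;
* species-abundance tables: ``site_id, species, count``, one row per
  species;
* trajectory exports: ``t, species, count`` (community) or
  ``t, individual_id, D`` (forest);
* fitted results and run configurations: JSON, parameter names exactly
  ``alpha, beta, lambda, m0, mmax, a, b``, with a ``spec_version`` field.

Fixture generation (`make_fixtures`) writes seeded synthetic data tables —
neutral-community abundances, truncated-Pareto size samples, and perturbed
size samples — together with a JSON sidecar recording the generating
parameters, which serves as ground truth for recovery tests.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream
from .distributions import TruncatedParetoSizeDist, sample_trunc_pareto

logger = logging.getLogger(__name__)

SPEC_VERSION = "1.0"

__all__ = [
    "read_individuals_table",
    "write_individuals_table",
    "read_abundance_table",
    "write_results_json",
    "make_fixtures",
    "RunConfig",
]


class RunConfig(dict):
    """A validated experiment configuration.

    A thin dict wrapper enforcing: a mandatory integer ``seed`` whenever the
    experiment is stochastic, and rejection of unknown keys against a
    declared schema.
    """

    KNOWN = {
        "experiment", "seed", "out", "J", "m", "S_meta", "t_max", "burn_in",
        "thin", "n_events", "theta", "g0", "n", "D_min", "D_max",
        "recruitment", "S", "C", "alpha", "reps", "lambda", "m0", "mmax",
        "scenario", "intensity", "threshold", "horizon", "sampling_interval",
        "n_boot", "spec_version",
    }

    def __init__(self, mapping, *, stochastic: bool = True):
        unknown = set(mapping) - self.KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if stochastic and "seed" not in mapping:
            raise ValueError("a seed is mandatory for stochastic experiments")
        super().__init__(mapping)

    @classmethod
    def from_json(cls, path, **kw) -> "RunConfig":
        with open(path) as fh:
            return cls(json.load(fh), **kw)

    def snapshot(self, out_dir) -> Path:
        """Write the fully resolved configuration next to the results."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "config.json"
        p.write_text(json.dumps({"spec_version": SPEC_VERSION, **self}, indent=2))
        return p


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_individuals_table(path) -> dict[str, np.ndarray]:
    """Read an individual-size table, returning sizes grouped by site.

    Validates columns, positivity of every size, and uniqueness of
    (site_id, individual_id); errors name the offending 1-based data row.
    """
    df = _read_table(path)
    required = {"site_id", "individual_id", "size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    bad = df.index[~(df["size"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive size at row {bad[0] + 1}")
    dup = df.duplicated(subset=["site_id", "individual_id"])
    if dup.any():
        raise ValueError(f"duplicate (site_id, individual_id) at row {df.index[dup][0] + 1}")
    return {
        str(site): grp["size"].to_numpy(dtype=float)
        for site, grp in df.groupby("site_id", sort=True)
    }


def write_individuals_table(path, sizes_by_site: dict[str, np.ndarray]) -> None:
    rows = []
    for site, sizes in sizes_by_site.items():
        for i, s in enumerate(np.asarray(sizes, dtype=float)):
            rows.append({"site_id": site, "individual_id": f"{site}-{i:06d}", "size": s})
    df = pd.DataFrame(rows)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_abundance_table(path) -> dict[str, pd.DataFrame]:
    """Read a species-abundance table grouped by site."""
    df = _read_table(path)
    required = {"site_id", "species", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if (df["count"] < 0).any():
        row = df.index[df["count"] < 0][0] + 1
        raise ValueError(f"negative count at row {row}")
    return {str(site): grp.reset_index(drop=True) for site, grp in df.groupby("site_id")}


def write_results_json(path, payload: dict) -> None:
    """Serialize fitted results with the versioned schema."""
    out = {"spec_version": SPEC_VERSION, **payload}

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(out, indent=2, default=default))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(kind: str, params: dict, seed: int, path) -> dict:
    """Write a seeded synthetic data table plus a JSON parameter sidecar.

    kinds
    -----
    ``sad``
        Neutral-community abundance counts at quasi-stationarity
        (params: J, m, S_meta, n_snapshots).
    ``sizes``
        Individual diameters from a truncated Pareto
        (params: lambda, m0, mmax, n).
    ``perturbed_sizes``
        As ``sizes``, then one Box-style pulse applied
        (params of ``sizes`` plus scenario in {b, d}, intensity,
        threshold_quantile); the sidecar records pre- and post-perturbation
        fitted parameters.
    """
    from .distributions import fit_trunc_pareto

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sidecar = path.with_suffix(path.suffix + ".json")

    if kind == "sad":
        from .community import NeutralCommunity, simulate_neutral_community

        model = NeutralCommunity(
            J=int(params.get("J", 500)),
            m=float(params.get("m", 0.1)),
            S_meta=int(params.get("S_meta", 25)),
        )
        n_snap = int(params.get("n_snapshots", 8))
        _, snaps = simulate_neutral_community(model, n_events=10 * model.J * n_snap, seed=seed)
        rows = []
        for t_idx, counts in enumerate(snaps):
            for sp, c in enumerate(counts):
                if c > 0:
                    rows.append(
                        {"site_id": f"snap{t_idx:03d}", "species": f"sp{sp:04d}", "count": int(c)}
                    )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        meta = {"kind": kind, "seed": seed, "J": model.J, "m": model.m, "S_meta": model.S_meta}

    elif kind in ("sizes", "perturbed_sizes"):
        dist = TruncatedParetoSizeDist(
            float(params.get("lambda", -2.0)),
            float(params.get("m0", 1.0)),
            float(params.get("mmax", 100.0)),
        )
        n = int(params.get("n", 5000))
        rng = stream(seed, "fixture-sizes")
        sizes = sample_trunc_pareto(dist, n, rng)
        meta = {"kind": kind, "seed": seed, **dist.to_dict(), "n": n}
        if kind == "perturbed_sizes":
            from .resilience import PerturbationSpec, apply_perturbation

            scenario = params.get("scenario", "b")
            intensity = float(params.get("intensity", 0.9))
            q = float(params.get("threshold_quantile", 25.0 if scenario == "b" else 90.0))
            thr = float(np.percentile(sizes, q))
            pkind = "remove_small" if scenario == "b" else "remove_large"
            pre_fit = fit_trunc_pareto(sizes)
            sizes = apply_perturbation(sizes, PerturbationSpec(pkind, intensity, thr), seed)
            post_fit = fit_trunc_pareto(sizes)
            meta.update(
                scenario=scenario, intensity=intensity, threshold=thr,
                pre_fit=pre_fit.to_dict(), post_fit=post_fit.to_dict(),
            )
        write_individuals_table(path, {"site0": sizes})
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    sidecar.write_text(json.dumps({"spec_version": SPEC_VERSION, **meta}, indent=2))
    logger.info("fixture %s written: %s (+sidecar)", kind, path)
    return meta
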