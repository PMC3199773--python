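"""End-to-end orchestration: filters -> statistics -> ABC -> (D, Z) -> MK -> windows.

All stages are pure functions of (inputs, config, seed); the run manifest
records the seed and a config hash so reports can be reproduced byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abcfit, dz_test, locus_io, mk, sumstats, windows

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    loci_dir: str
    metadata: str
    annotation: str
    out_dir: str
    policy: locus_io.SiteFilterPolicy = field(default_factory=locus_io.SiteFilterPolicy)
    abc: abcfit.ABCConfig = field(default_factory=abcfit.ABCConfig)
    n_null_sims: int = 10_000
    p_mis: float = dz_test.DEFAULT_P_MIS
    window_width: int = 500
    window_step: int = 50
    pvalue_method: str = "density"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policy = locus_io.SiteFilterPolicy(**raw.pop("policy", {}))
        abc = abcfit.ABCConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.pop("abc", {}).items()})
        return cls(policy=policy, abc=abc, **raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_loci(config: RunConfig) -> tuple[list[locus_io.AlignedLocus], pd.DataFrame, pd.DataFrame]:
    meta = locus_io.read_metadata(config.metadata)
    ann = locus_io.read_annotation(config.annotation)
    loci = []
    for path in sorted(Path(config.loci_dir).glob("*.fasta")):
        loci.append(locus_io.read_locus(path, meta, ann))
    if not loci:
        raise FileNotFoundError(f"no FASTA loci under {config.loci_dir}")
    return loci, meta, ann


def filter_all(loci, policy) -> dict[str, locus_io.FilteredLocus]:
    filtered = {}
    for locus in loci:
        try:
            filtered[locus.locus_id] = locus_io.mask_sites(locus, policy)
        except locus_io.EmptyLocusError as exc:
            log.warning("skipping locus: %s", exc)
    return filtered


def stats_table(
    filtered: dict[str, locus_io.FilteredLocus],
    strict_filtered: dict[str, locus_io.FilteredLocus] | None = None,
) -> pd.DataFrame:
    """Per-locus diversity rows for the whole sample and each group.

    Columns follow the survey-style summary: n, L, S, theta_w, pi, D, Z,
    plus (whole scope) Hudson-style F_ST between the two groups, and
    Hudson's rho computed on the strict (complete-data) site mask when a
    strict view is supplied.
    """
    rows = []
    for lid, fl in filtered.items():
        scopes = {"whole": None}
        accs = np.array(fl.retained)
        groups = fl.groups()
        for g in (1, 2):
            scopes[f"group{g}"] = list(accs[groups == g])
        strict = (strict_filtered or {}).get(lid)
        for scope, accessions in scopes.items():
            if accessions is not None and len(accessions) < 2:
                continue
            st = locus_io.locus_diversity(fl, accessions)
            fst = math.nan
            if scope == "whole" and min(np.sum(groups == 1), np.sum(groups == 2)) >= 2:
                m = np.where(fl.locus.matrix(fl.retained) < 0, -1, fl.locus.matrix(fl.retained))
                fst, _, _ = sumstats.fst_hudson(m[:, fl.site_mask], groups)
            rho = math.nan
            if strict is not None and strict.L_analysed >= 2:
                sub = [a for a in strict.retained if accessions is None or a in set(accessions)]
                if len(sub) >= 2:
                    rho = sumstats.hudson_rho(strict.site_matrix()[
                        [strict.retained.index(a) for a in sub]
                    ])
            rows.append(
                {
                    "locus_id": lid,
                    "scope": scope,
                    "n": st.n,
                    "L": st.L,
                    "S": st.S,
                    "theta_w": st.theta_w,
                    "pi": st.pi,
                    "D": st.D,
                    "Z": st.Z,
                    "fst": fst,
                    "rho": rho,
                    "oriented": st.oriented,
                }
            )
    return pd.DataFrame(rows)


def group_maf_values(filtered, accessions_of_group) -> list[np.ndarray]:
    """Per-locus folded MAF vectors for one group (pooled later by abcfit)."""
    out = []
    for fl in filtered.values():
        accs = [a for a in fl.retained if a in accessions_of_group]
        if len(accs) < 2:
            continue
        m = fl.locus.matrix(accs)
        m = np.where(m < 0, -1, m)
        mafs = []
        for col in np.where(fl.site_mask)[0]:
            obs = m[:, col][m[:, col] >= 0]
            if obs.size < 2:
                continue
            cnt = np.bincount(obs, minlength=4)
            alleles = np.where(cnt > 0)[0]
            if alleles.size == 2:
                mafs.append(cnt[alleles].min() / obs.size)
        out.append(np.array(mafs))
    return out


def group_layout(filtered, accessions_of_group) -> list[tuple[int, int]]:
    """Per-locus (n, L) pairs replicated by the ABC sampler."""
    layout = []
    for fl in filtered.values():
        n = len([a for a in fl.retained if a in accessions_of_group])
        if n >= 2 and fl.L_analysed >= 1:
            layout.append((n, fl.L_analysed))
    return layout


ALL_STAGES = ("stats", "dz", "mk", "windows")


def mk_fit_stage(strict_filtered: dict[str, locus_io.FilteredLocus], out: Path) -> pd.DataFrame:
    """MK counts on the strict mask and the M0-M5 comparison tables."""
    cat_of = {"CONT": 1, "FLOW": 2, "SYMB": 3}
    counts = []
    for lid, fl in strict_filtered.items():
        if not fl.oriented or not fl.locus.exons:
            continue
        coding = locus_io.classify_coding_sites(fl.locus, fl)
        if coding.Ln + coding.Ls <= 0:
            continue
        counts.append(mk.mk_counts(fl, coding, lid, cat_of.get(lid[:4], 1)))
    if not counts:
        log.warning("no loci with analysable coding sites; MK stage skipped")
        return pd.DataFrame()
    mk.counts_frame(counts).to_csv(out / "mk_counts.tsv", sep="\t", index=False)
    fits = mk.fit_all(counts)
    frame = mk.fits_frame(fits)
    frame.to_csv(out / "mk_fits.tsv", sep="\t", index=False, na_rep="NA")
    return frame


def windows_stage(
    filtered: dict[str, locus_io.FilteredLocus],
    strict_filtered: dict[str, locus_io.FilteredLocus],
    loci_ids: list[str],
    width: int,
    step: int,
    out: Path,
) -> pd.DataFrame:
    """Sliding-window tables for the requested loci."""
    frames = []
    for lid in loci_ids:
        fl = filtered[lid]
        coding = None
        if lid in strict_filtered and fl.locus.exons:
            coding = locus_io.classify_coding_sites(fl.locus, strict_filtered[lid])
        ws = windows.sliding_windows(fl, coding, width, step)
        frames.append(windows.windows_frame(lid, ws))
    table = pd.concat(frames) if frames else pd.DataFrame()
    if len(table):
        table.to_csv(out / "windows.tsv", sep="\t", index=False, na_rep="NA")
    return table


def run_all(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the scan (or a subset of stages); returns an output manifest.

    ``stages`` subsets {"stats", "dz", "mk", "windows"}; "dz" implies the
    ABC fits, and "windows" scans the loci flagged by "dz" (or none).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    loci, meta, ann = load_loci(config)
    group_accs = {
        g: set(meta.loc[meta["group"] == g, "accession_id"].astype(str)) for g in (1, 2)
    }

    filtered = filter_all(loci, config.policy)
    strict_filtered = filter_all(loci, locus_io.SiteFilterPolicy.strict())
    stats = stats_table(filtered, strict_filtered)
    stats.to_csv(out / "stats.tsv", sep="\t", index=False, na_rep="NA")

    # control loci drive the demographic fit
    control_ids = [lid for lid in filtered if lid.startswith("CONT")] or list(filtered)
    controls = {lid: filtered[lid] for lid in control_ids}

    results = {1: [], 2: []}
    theta_cut = {}
    for g in (1, 2) if "dz" in stages else ():
        layout = group_layout(controls, group_accs[g])
        obs = abcfit.observed_summaries(
            group_maf_values(controls, group_accs[g]),
            total_sites=sum(L for _, L in layout),
        )
        table = abcfit.abc_sample(config.abc, layout, rng)
        grid = abcfit.abc_posterior(obs, table, config.abc)
        grid.to_frame().to_csv(out / f"posterior_group{g}.tsv", sep="\t", index=False)
        # flag loci whose theta exceeds the control 95th percentile (Z caution)
        tw = stats.loc[(stats["scope"] == f"group{g}") & stats["locus_id"].isin(control_ids), "theta_w"]
        theta_cut[g] = float(np.nanpercentile(tw, 95)) if len(tw) else math.inf
        group_res = []
        for lid, fl in filtered.items():
            accs = [a for a in fl.retained if a in group_accs[g]]
            if len(accs) < 4 or fl.L_analysed < 1:
                continue
            st = locus_io.locus_diversity(fl, accs)
            flag_no_poly = st.S == 0
            flag_unor = not st.oriented
            p = math.nan
            if not (flag_no_poly or flag_unor):
                null = dz_test.build_null(
                    lid, st.n, st.L, grid, config.n_null_sims, config.p_mis, rng
                )
                p = dz_test.dz_pvalue(st.D, st.Z, null, method=config.pvalue_method)
            group_res.append(
                dz_test.DZResult(
                    locus_id=lid,
                    group=g,
                    D=st.D,
                    Z=st.Z,
                    p_value=p,
                    unoriented=flag_unor,
                    no_polymorphism=flag_no_poly,
                    high_theta_warning=st.theta_w > theta_cut[g],
                )
            )
        results[g] = group_res

    r = pv = math.nan
    nshared = 0
    flagged: list[str] = []
    dz_frame = pd.DataFrame()
    if "dz" in stages:
        dz_frame = dz_test.results_frame(results[1], results[2])
        dz_frame.to_csv(out / "dz_results.tsv", sep="\t", index=False, na_rep="NA")
        r, pv, nshared = dz_test.cross_group_correlation(
            dz_frame.get("P1", pd.Series(dtype=float)), dz_frame.get("P2", pd.Series(dtype=float))
        )
        flagged = dz_frame.loc[
            (dz_frame.get("P1", pd.Series(dtype=float)) < 0.05)
            | (dz_frame.get("P2", pd.Series(dtype=float)) < 0.05),
            "locus_id",
        ].tolist()

    if "mk" in stages:
        mk_fit_stage(strict_filtered, out)

    if "windows" in stages and flagged:
        windows_stage(
            filtered, strict_filtered, flagged, config.window_width, config.window_step, out
        )

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_loci": len(loci),
        "cross_group_correlation": r,
        "cross_group_correlation_p": pv,
        "n_shared_loci": nshared,
        "flagged_loci": flagged,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
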