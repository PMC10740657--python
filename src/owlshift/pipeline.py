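"""High-level pipeline stages tying the modules together.

Each stage reads what the previous one wrote under a run directory, does
one piece of the analysis, and writes plain-text outputs (CSV tables,
ASCII-grid rasters, GeoJSON points) plus a manifest echoing its inputs and
seed, so a run is reproducible from the manifest alone.  The command-line
interface and the numbered analysis scripts are both thin wrappers over
these functions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .habitat import (SpeciesProfile, change_summary, capture_records,
                      load_species_profiles, overlay_territories,
                      profile_retention, render_habitat, transition_matrix)
from .landscape import HabitatMap, buffer_mask, extent_ha, patch_statistics
from .projection import project_landscape
from .synthetic import (SyntheticConfig, fit_envelopes, generate_climate,
                        generate_landscape, generate_occurrences,
                        generate_territories, territory_transition_fixture)
from .taxonomy import (FOREST_WOODLAND_ZONES, Taxonomy, default_generalization,
                       default_taxonomy)
from .validation import mcnemar, one_tailed_z, randomization_null

__all__ = [
    "run_simulate", "run_project", "run_habitat", "run_validate",
    "run_territories", "run_all",
]


def _manifest(outdir: Path, stage: str, payload: dict) -> None:
    from . import __version__
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "package_version": __version__, **payload}
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def run_simulate(config: SyntheticConfig, outdir) -> dict:
    """Generate and persist the synthetic world: landscape, climate
    (current + 2090), envelopes, and per-species occurrences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy = default_taxonomy()
    landscape = generate_landscape(config, taxonomy)
    climate_now = generate_climate(landscape, config, warmed=False)
    climate_2090 = generate_climate(landscape, config, warmed=True)
    envelopes = fit_envelopes(landscape, climate_now, config.interannual_sd(),
                              taxonomy=taxonomy)
    oio.write_landscape(outdir / "landscape", landscape, taxonomy)
    for tag, clim in (("current", climate_now), ("2090", climate_2090)):
        for v, arr in clim.items():
            oio.write_ascii_grid(outdir / "landscape" / f"climate_{tag}_{v}.asc",
                                 arr, landscape.cell_size)
    oio.write_envelopes(outdir / "envelopes.csv", envelopes)
    profiles = load_species_profiles(landscape=landscape)
    occurrences = {}
    for name, prof in profiles.items():
        hab = render_habitat(prof, landscape)
        if hab.mask.any():
            recs = generate_occurrences(prof, hab, landscape, config, taxonomy)
            occurrences[name] = recs
            oio.write_points_geojson(outdir / f"occurrences_{name}.geojson", recs)
    _manifest(outdir, "simulate", {
        "seed": config.seed, "config": dataclasses.asdict(config),
        "n_cells": landscape.n_cells,
        "eru_ids": landscape.eru_ids_present(),
        "n_occurrence_records": {k: len(v) for k, v in occurrences.items()},
    })
    return {"landscape": landscape, "climate_now": climate_now,
            "climate_2090": climate_2090, "envelopes": envelopes,
            "profiles": profiles, "occurrences": occurrences,
            "taxonomy": taxonomy, "config": config}


def run_project(state: dict, outdir, k: float = 2.0, method: str = "mean") -> dict:
    """Project the landscape to 2090 and persist the projection rasters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = state["landscape"]
    taxonomy = state["taxonomy"]
    projection = project_landscape(landscape, state["climate_2090"],
                                   state["envelopes"], taxonomy, k=k,
                                   method=method)
    codes = {e: i + 1 for i, e in enumerate(projection.eru_order)}
    ml = np.vectorize(codes.get)(projection.most_likely)
    oio.write_ascii_grid(outdir / "projected_most_likely.asc", ml,
                         landscape.cell_size)
    vs = np.round(np.nan_to_num(projection.current_vs * 1000,
                                nan=-9999)).astype(int)
    oio.write_ascii_grid(outdir / "current_eru_vs_x1000.asc", vs,
                         landscape.cell_size)
    recovery = None
    if state["config"].warming_offset_m == 0:
        recovery = float(projection.candidates_contain_current().mean())
    _manifest(outdir, "project", {
        "seed": state["config"].seed, "k": k, "method": method,
        "mean_candidates_per_cell": float(projection.candidate_count().mean()),
        "zero_warming_recovery_fraction": recovery,
    })
    state = dict(state)
    state["projection"] = projection
    return state


def run_habitat(state: dict, outdir, mode: str = "inclusive",
                connectivity: str = "rook") -> dict:
    """Render per-species current/projected habitat, change table, patches."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = state["landscape"]
    rows, patch_rows = [], []
    maps = {}
    for name, prof in state["profiles"].items():
        cur = render_habitat(prof, landscape)
        proj = render_habitat(prof, landscape, state["projection"], mode=mode)
        maps[name] = (cur, proj)
        oio.write_mask(outdir / f"habitat_current_{name}.asc", cur)
        oio.write_mask(outdir / f"habitat_2090_{name}.asc", proj)
        cs = change_summary(cur, proj, species=name)
        rows.append({
            "species": name,
            "current_ha": cs.current_ha, "projected_ha": cs.projected_ha,
            "pct_change_raw": cs.pct_change_raw,
            "pct_change_rounded": cs.pct_change_rounded,
            "persisted_ha": cs.persisted_ha, "gained_ha": cs.gained_ha,
            "lost_ha": cs.lost_ha,
        })
        for tag, m in (("current", cur), ("2090", proj)):
            ps = patch_statistics(m, connectivity=connectivity)
            patch_rows.append({
                "species": name, "epoch": tag, "connectivity": connectivity,
                "patch_count": ps.count, "total_ha": ps.total_ha,
                "min_ha": ps.min_ha, "max_ha": ps.max_ha,
                "mean_ha": ps.mean_ha, "sd_ha": ps.sd_ha,
            })
    change = pd.DataFrame(rows)
    patches = pd.DataFrame(patch_rows)
    change.to_csv(outdir / "habitat_change.csv", index=False, na_rep="NA")
    patches.to_csv(outdir / "patch_statistics.csv", index=False, na_rep="NA")
    _manifest(outdir, "habitat", {
        "seed": state["config"].seed, "mode": mode,
        "connectivity": connectivity, "n_species": len(rows),
    })
    state = dict(state)
    state.update(habitat_maps=maps, change_table=change, patch_table=patches)
    return state


def run_validate(state: dict, outdir, iterations: int = 500,
                 buffer_m: float = 1000.0, mode: str = "inclusive") -> dict:
    """Randomization nulls + z-tests (capture table) and McNemar change
    tests per species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = state["landscape"]
    taxonomy = state["taxonomy"]
    config = state["config"]
    sampling = landscape.eru_mask(
        taxonomy.subset_ids(zones=set(FOREST_WOODLAND_ZONES)))
    cap_rows, mc_rows = [], []
    for name, prof in state["profiles"].items():
        recs = state["occurrences"].get(name)
        if not recs:
            continue
        cur, proj = state["habitat_maps"][name]
        zone_samp = sampling & landscape.zone_mask(prof.zone_ids)
        cc = capture_records(recs, cur, buffer_distance=buffer_m)
        for with_buffer in (False, True):
            observed = cc.within_model + (cc.within_buffer_only if with_buffer
                                          else 0)
            hab = buffer_mask(cur, buffer_m).mask if with_buffer else cur.mask
            rr = randomization_null(len(recs), zone_samp, hab, observed,
                                    iterations=iterations,
                                    seed=config.seed + 7)
            z, p, degen = one_tailed_z(observed, len(recs), rr.null_counts)
            cap_rows.append({
                "species": name, "with_buffer": with_buffer,
                "within_model": cc.within_model,
                "within_buffer_only": cc.within_buffer_only,
                "outside": cc.outside, "total": cc.total,
                "observed_captures": observed,
                "sims_outperform": rr.outperform, "iterations": iterations,
                "z": z, "p_one_tailed": p, "degenerate": degen,
            })
        # paired in/out state per record, current vs projected
        cur_b = buffer_mask(cur, buffer_m)
        proj_b = buffer_mask(proj, buffer_m)
        for with_buffer in (True, False):
            cm = cur_b if with_buffer else cur
            pm = proj_b if with_buffer else proj
            in_cur, in_proj = [], []
            for r in recs:
                cell = landscape.cell_of_point(r.x, r.y)
                in_cur.append(bool(cell and cm.mask[cell]))
                in_proj.append(bool(cell and pm.mask[cell]))
            in_cur = np.array(in_cur); in_proj = np.array(in_proj)
            a = int((in_cur & in_proj).sum()); b = int((in_cur & ~in_proj).sum())
            c = int((~in_cur & in_proj).sum()); d = int((~in_cur & ~in_proj).sum())
            res = mcnemar(b, c, a=a, d=d)
            mc_rows.append({
                "species": name, "with_buffer": with_buffer,
                "n": len(recs), "a_in_in": a, "b_in_out": b,
                "c_out_in": c, "d_out_out": d,
                "chi2": None if res.chi2 is None else round(res.chi2, 2),
                "p": None if res.p is None else round(res.p, 4),
                "correction_applied": res.correction_applied,
            })
    captures = pd.DataFrame(cap_rows)
    mcn = pd.DataFrame(mc_rows)
    captures.to_csv(outdir / "model_validation.csv", index=False, na_rep="NA")
    mcn.to_csv(outdir / "mcnemar_tests.csv", index=False, na_rep="NA")
    _manifest(outdir, "validate", {
        "seed": config.seed, "iterations": iterations, "buffer_m": buffer_m,
        "n_rows": len(cap_rows),
    })
    state = dict(state)
    state.update(capture_table=captures, mcnemar_table=mcn)
    return state


def run_territories(state: dict, outdir, species: str = "flammulated_owl",
                    n: int = 148) -> dict:
    """Territory overlay on the projection, transition matrix, retention."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = state["landscape"]
    config = state["config"]
    prof = state["profiles"][species]
    cur = render_habitat(prof, landscape)
    terr = generate_territories(prof, cur, landscape, config, n=n)
    gen = default_generalization()
    terr = overlay_territories(terr, landscape, state["projection"], gen)
    tm = transition_matrix(terr)
    profile_labels = {gen[e] for e in prof.eru_ids if e in gen}
    pct_cur, pct_rem, pct_pj = profile_retention(
        tm, profile_labels, {"Pinyon-Juniper", "Madrean Woodland"})
    tm.with_totals().to_csv(outdir / f"territory_transitions_{species}.csv",
                            na_rep="NA")
    oio.write_points_geojson(outdir / f"territories_{species}.geojson", terr)
    _manifest(outdir, "territories", {
        "seed": config.seed, "species": species, "n_territories": len(terr),
        "pct_currently_in_profile": pct_cur,
        "pct_remaining_in_profile": pct_rem,
        "pct_to_pinyon_juniper_or_madrean": pct_pj,
    })
    state = dict(state)
    state.update(territories=terr, transition=tm,
                 retention=(pct_cur, pct_rem, pct_pj))
    return state


def run_all(config: SyntheticConfig, outdir, iterations: int = 500) -> dict:
    """The full pipeline in order, one output directory."""
    outdir = Path(outdir)
    state = run_simulate(config, outdir)
    state = run_project(state, outdir)
    state = run_habitat(state, outdir)
    state = run_validate(state, outdir, iterations=iterations)
    state = run_territories(state, outdir)
    return state
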