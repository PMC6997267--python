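"""End-to-end workflow: simulate -> aggregate -> rates -> Gi* -> chi-squared.

`run_all` chains the full analysis on a synthetic geography and cohort and
returns (and optionally writes) a structured report: per-outcome overall
rates, hot/cold spot summaries and deprivation-quintile chi-squared tests.
"""

from __future__ import annotations

import json
from pathlib import Path

from .association import AssociationError
from .cohort import AnalysisWindow, aggregate
from .geo_io import write_zones
from .hotspot import HotspotModel
from .rates import round1, zone_rates
from .simulate import SimulationConfig, simulate
from .weights import fixed_distance_band, hybrid_weights, queen_contiguity

#: outcomes analysed by the standard workflow, with their windows
STANDARD_OUTCOMES = ("dfu", "lea", "death_after_dfu", "death_after_lea")


def build_weights(zones, scheme: str = "hybrid", threshold="auto"):
    """Construct the requested weights scheme for a geography."""
    if scheme == "queen":
        return queen_contiguity(zones)
    band = fixed_distance_band(zones, threshold=threshold)
    if scheme == "distance_band":
        return band
    if scheme == "hybrid":
        return hybrid_weights(band, queen_contiguity(zones))
    raise ValueError(f"unknown weights scheme {scheme!r}")


def run_all(
    config: SimulationConfig,
    out_dir=None,
    weights_scheme: str = "hybrid",
    threshold="auto",
    expected: str = "zones",
    outcomes=STANDARD_OUTCOMES,
    render: bool = False,
) -> dict:
    """Run the full synthetic workflow and return the report dict.

    When ``out_dir`` is given, writes: zones.geojson (with rates and bins
    as properties), cohort.csv, per-outcome rates and spots CSVs, weights
    summary JSON, report.json, and (``render=True``) SVG maps.
    """
    zones, surface, cohort_df = simulate(config)
    weights = build_weights(zones, scheme=weights_scheme, threshold=threshold)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort_df_out = cohort_df
        from .cohort import write_cohort_csv

        write_cohort_csv(cohort_df_out, out_dir / "cohort.csv")
        weights.to_summary_json(out_dir / "weights_summary.json")
        weights.to_pairs_csv(out_dir / "weights_pairs.csv")

    report: dict = {
        "config": {
            "n_zones": config.n_zones,
            "mean_population": config.mean_population,
            "seed": config.seed,
            "deprivation_smoothness": config.deprivation_smoothness,
            "quintile_relative_risks": list(config.quintile_relative_risks),
            "weights_scheme": weights_scheme,
            "distance_band_threshold": weights.threshold,
            "expected_model": expected,
        },
        "cohort_size": int(len(cohort_df)),
        "outcomes": {},
    }
    zone_props = {}
    for outcome in outcomes:
        window = AnalysisWindow.dfu_subset() if outcome == "dfu" else AnalysisWindow.full()
        table = aggregate(cohort_df, zones, outcome, window)
        rt = zone_rates(table)
        res = HotspotModel.from_rates(rt, weights).fit()
        summ = res.spot_summary()
        entry = {
            "window": window.label,
            "numerator": table.numerator_total,
            "denominator": table.denominator_total,
            "overall_rate": rt.overall,
            "overall_rate_1dp": round1(rt.overall),
            "rate_kind": rt.kind,
            "spots": summ,
            "chi_square": {},
        }
        for which in ("hot", "cold"):
            try:
                chi = res.quintile_association(zones, which=which, expected=expected)
                entry["chi_square"][which] = chi.to_dict()
            except AssociationError as exc:
                entry["chi_square"][which] = {"error": str(exc)}
        report["outcomes"][outcome] = entry

        bins = res.bins.reindex(zones.zone_ids, fill_value="not_significant")
        zone_props[f"{outcome}_rate"] = [None if v != v else float(v) for v in rt.values]
        zone_props[f"{outcome}_bin"] = list(bins.to_numpy())
        if out_dir is not None:
            rt.to_csv(out_dir / f"rates_{outcome}.csv")
            res.to_csv(out_dir / f"spots_{outcome}.csv")
            if render:
                res.plot(zones, path=out_dir / f"map_{outcome}.svg", title=outcome)

    if out_dir is not None:
        write_zones(zones.replace(extra=zone_props), out_dir / "zones.geojson")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
    return report
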