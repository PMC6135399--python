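"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from chiagrow import accumulate_gdd, generate_weather, irrigation_design, sowing_date_design

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"
SEED = 1

DESIGNS = {"sowing_date": sowing_date_design, "irrigation": irrigation_design}


def outdir(trial: str) -> Path:
    d = RESULTS / trial
    d.mkdir(parents=True, exist_ok=True)
    return d


def trial_weather(design, seed: int = SEED):
    """The site weather series covering every treatment's season."""
    import datetime as dt

    first = min(t.sowing_date for t in design.treatments)
    last = max(
        t.sowing_date + dt.timedelta(days=design.season_days) for t in design.treatments
    )
    return generate_weather(design.site, first, (last - first).days + 1, seed=seed)


def trial_thermal(design, weather):
    return {
        t.label: accumulate_gdd(weather, start_date=t.sowing_date)
        for t in design.treatments
    }
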