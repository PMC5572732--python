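"""Run the whole chain: simulate -> screen -> analyze -> report.

Produces every stage table (sessions.csv, criteria.csv, screening.csv,
choice.csv, epm.csv, bal.csv), a stats_report.json and a plain-text report
under ./pipeline_demo, then prints the report. Identical configs reproduce
byte-identical bundles.
"""

import warnings

import threecrit as tc
from threecrit.pipeline import format_report

warnings.filterwarnings("ignore", category=UserWarning)  # above-99th-pct notes

config = tc.RunConfig(seed=1, output_dir="pipeline_demo")
bundle = tc.run_pipeline(config)

print(format_report({"provenance": bundle.provenance, **bundle.stats_report}))
print(f"bundle hash (pure function of the config): {bundle.bundle_hash[:16]}...")
print()
print("The simulated cohort reproduces the reference study's structure: four")
print("criterion-count groups ordered on every measure, a single retained")
print("factor, an anxious vulnerable group, and a null BAL group difference.")
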