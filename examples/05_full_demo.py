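"""End-to-end demo: every preset, every analysis stage, one JSON report.

Writes CSV tables and summary.json (deterministic for a given seed) under
demo_out/ and prints the parameter-recovery benchmark results.
"""

from xenovocal.demo import RunConfig, run_demo

summary = run_demo(RunConfig(seed=1, output_dir="demo_out"))
print(f"xenovocal {summary['package_version']} demo (seed 1)")
for name, entry in summary["benchmarks"].items():
    print(f"  {name:32s} value {entry['value']:>9.3f}  "
          f"expected {entry['expected']:>7.3f}  "
          f"{'pass' if entry['passed'] else 'FAIL'}")
print(f"all benchmarks passed: {summary['benchmarks_all_passed']}")
print("tables written to demo_out/ (audio_click_rates.csv, petersii_phases.csv,")
print("potentiation_fits.csv, summary.json)")
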