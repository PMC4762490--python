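"""End-to-end run: rendered stacks -> biomarkers -> statistics -> SVM.

Generates a small demo cohort of rendered plate-phantom stacks (two
species archetypes parameterized from the modern corpus means), then runs
the whole pipeline from the TOML config it wrote.
"""

import tempfile
from pathlib import Path

from cervidct import RunConfig, make_demo_dataset, run

with tempfile.TemporaryDirectory() as tmp:
    config_path = make_demo_dataset(Path(tmp) / "demo", seed=1, n_per_species=3)
    print(f"demo cohort written under {config_path.parent}")

    report = run(RunConfig.from_toml(config_path))

    print(f"\n{len(report.samples)} samples profiled, "
          f"{len(report.exclusions)} excluded")
    print("sample        threshold   Tb.Th (mm)  Tb.Sp (mm)  BV/TV (%)")
    for s in report.samples:
        d, p = s["diagnostics"], s["profile"]
        print(f"  {s['sample_id']:12s}  {d['threshold_level']:7.1f}   "
              f"{p['tb_th']:8.4f}  {p['tb_sp']:9.4f}  {p['bv_tv']:8.2f}")

    cls = report.aggregates["classification"]
    print(f"\nLOOCV with selected c={cls['selected_c']}, "
          f"gamma={cls['selected_gamma']}: "
          f"{cls['loocv']['overall_percent']}% correct")
    print("ranking:", ", ".join(report.aggregates["variable_ranking"]))
    print("\nThe two archetypes differ by far more than the render noise, so "
          "the cohort separates perfectly; report.json holds every number "
          "traceable to its stage.")
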