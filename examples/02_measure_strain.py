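"""Measure longitudinal strain for one study, end to end.

Builds a phantom with the default artefacts (papillary muscles,
surface texture, frame noise), runs the full pipeline — reslice each
long-axis plane at every phase, extract the mitral-opened endocardial
contour, measure its length by the three methods — and prints the
per-view results.
"""

from ctstrain import PhantomSpec, StudyRecord, generate_phantom, run_study

cine, planes, truth = generate_phantom(PhantomSpec(seed=7))
record = StudyRecord("example-study", volumes=cine, planes=planes)
result, rows = run_study(record)

print(rows.to_string(index=False,
                     float_format=lambda v: f"{v:.3f}"))
print()
print(f"EF {result.ef:.3f} (truth {truth.ef:.3f}); "
      f"ED phase {result.ed}, ES phase {result.es}")
for view, per_method in result.ls.items():
    print(f"{view}: truth LS {truth.ls[view]:+.3f} | "
          + "  ".join(f"{m} {v:+.3f}" for m, v in per_method.items()))
# LS is negative (shortening); the naive method drifts from the truth
# under papillary/texture artefacts while the spline tracks it closely.
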