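"""End-to-end demo at a small scale: simulate -> train -> evaluate -> plot.

Equivalent to ``voiceinv demo``.  Writes model archives, JSON reports,
and two figures (predicted-vs-truth scatter, Ps track with CI band)
into ``voiceinv_demo/``, then prints the Table-style summary for both
back-ends.
"""
import voiceinv as vi

config = vi.PipelineConfig(
    seed=1,
    n_rows=2000,
    n_members=5,
    outdir="voiceinv_demo",
    train=vi.TrainConfig(max_epochs=60, patience=10),
)
reports = vi.run_demo(config)

for name in ("ensemble", "bnn", "protocol_ensemble", "protocol_bnn"):
    print(f"--- {name}")
    print(reports[name].render_table())
print("Reports and figures are in voiceinv_demo/ (scatter_ps.png, ps_track.png).")
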