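"""Run the full perfusion pipeline on a synthetic study with an LAD deficit.

Generates a dynamic short-axis phantom whose anterior/anteroseptal wedge
perfuses at 150 mL/min/100 g against a 300 mL/min/100 g remote myocardium
(10 HU noise, one-voxel breathing motion), then runs aorta ROI detection,
registration, fallback segmentation, beam-hardening correction, SLICR MBF
mapping, polar-map conversion and the AHA-16 report, and classifies the
patient given a CAD-RADS 4 reading of the LAD.
"""

from ccperf import (PhantomConfig, PipelineConfig, SectorTruth, build_phantom,
                    run_pipeline)

config = PhantomConfig(
    noise_sd_hu=10.0, motion_amplitude_vox=1, septal_angle_deg=300.0,
    sectors=(SectorTruth(300, 360, 0, 10 ** 6, mbf=150.0),
             SectorTruth(0, 300, 0, 10 ** 6, mbf=300.0)))
study = build_phantom(config, seed=11)

result = run_pipeline(
    PipelineConfig(cadrads={"LAD": 4, "RCA": 0, "LCX": 0},
                   septal_angle_deg=300.0),
    study)

print("stage status :", ", ".join(
    f"{s['name']}={s['status']}" for s in result.manifest["stages"]))
for vessel, t in result.territories.items():
    flag = "ischemic" if t.value < 200.0 else "preserved"
    print(f"{vessel}: representative MBF {t.value:6.1f} mL/min/100g "
          f"(adjacent pair {t.pair}) -> {flag}")
print("patient classification:", result.classification.label)
print("The LAD territory (truth 150) reads well below the 200 mL/min/100g")
print("cutoff while RCA/LCX stay near 300; with an obstructive CAD-RADS 4")
print("LAD this is flow-limiting stenosis, not microvascular disease.")
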