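"""Simulate one dual-isotope acquisition and reconstruct it both ways.

Takes the ~6%-contamination experiment (3.1 GBq 90Y + 189 MBq 99mTc, HE
collimator, 25 min), simulates the three windows with Poisson noise, then
reconstructs the 160-200 keV window with plain OSEM (attenuation only,
5 mm post-filter) and with the model-compensating reconstruction
(attenuation + collimator response + crosstalk term), and compares the
37 mm sphere contrast recovery.
"""
from dataclasses import replace

import bremspect as bs
from bremspect.reconstruction import advanced_config, local_site_config
from bremspect.study import StudyConfig, _grid, build_row_maps

cfg = StudyConfig()  # default desk-scale study conditions
geom = bs.build_phantom_geometry(axial_length=cfg.axial_length_mm)
grid = _grid(cfg)
window = bs.STUDY_WINDOWS[1]  # 160-200 keV
mu = bs.voxelize_attenuation(geom, grid, (window.low + window.high) / 2)

row = bs.load_schedule()[4]  # experiment 5: 6% Tc, HE, 25 min
print(f"experiment {row.exp_id}: {row.aeff_y90_gbq} GBq 90Y + "
      f"{row.aeff_tc_mbq} MBq 99mTc ({row.percent_tc}%), {row.collimator_kind}")

maps = build_row_maps(geom, grid, row)
protocol = bs.AcquisitionProtocol(
    collimator=bs.collimator_by_kind(row.collimator_kind),
    windows=(window,), scan_time_min=row.scan_time_min, n_views=cfg.n_views,
)
mu_maps = {window.label: mu}
sino = bs.simulate_experiment(row, maps, mu_maps, protocol, seed=17)[0]
wi = sino.window_index(window)
print(f"simulated counts in {window.label} keV: {sino.counts[wi].sum():,}")

# plain OSEM, attenuation only, 5 mm post-filter
plain_sys = bs.SystemModel(grid, n_views=cfg.n_views, mu=mu,
                           attenuation=True, cdr=False, septal=False, flat=False)
plain = bs.postfilter(bs.osem(sino, window, plain_sys, local_site_config()), 5.0)

# model-compensating reconstruction with the oracle Tc crosstalk estimate
tc_iso = next(i for i in maps if i.name == "Tc99m")
tc_expected = bs.forward_project(maps[tc_iso], mu, protocol, window, tc_iso)
adv = bs.advanced_recon(sino, window, {"mu": mu, "tc_expected": tc_expected},
                        advanced_config())

vois = bs.build_vois(geom, grid)
crc_plain = bs.compute_crc(plain, vois).crc_mean
crc_adv = bs.compute_crc(adv, vois).crc_mean
print("\nsphere  CRC(OSEM)  CRC(compensated)")
for d in bs.DEFAULT_REPORT_SPHERES_MM:
    print(f"{d:4.0f} mm  {crc_plain[d]:8.3f}  {crc_adv[d]:10.3f}")
print("\nCRC = ((C_S/C_B) - 1)/(R - 1): 1 is perfect contrast recovery, 0 means")
print("the sphere is indistinguishable from background. Modelling the collimator")
print("response and crosstalk roughly doubles the recovered contrast.")
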