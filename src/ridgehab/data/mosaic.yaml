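# Packaged MOSAiC July configuration: keel morphology, level-ice
# thicknesses, areal coverages, and per-compartment Chl-a / POC
# concentration estimates (mean, SE, n) for the drifting-station floe.
morphology:
  keel_depth: 3.9            # m, mean keel depth (ROV multibeam)
  consolidated_thickness: 2.2  # m (drilling, n=8)
  macroporosity: 0.17        # rubble void fraction (drilling, n=8)
  block_thickness: 0.3       # m (tape measurements)
  # block_length defaults to 3.5 x block_thickness
  exterior_skin: 0.1         # m, per block face
  bottom_layer: 0.1          # m, all ice types

level_ice:
  # Drafts, m below the waterline.  Buoy thicknesses are 1.4 m (FYI) and
  # 1.5 m (SYI); times the 0.9 submerged fraction and rounded to the
  # 0.1 m core-section resolution these give 1.3 and 1.4 m of submerged,
  # habitable column (freeboard is excluded from habitat volumes).
  fyi_draft: 1.3
  syi_draft: 1.4
  bottom_layer: 0.1

cover:
  ridge: 0.22                # areal fractions from airborne laser scanning
  fyi: 0.50
  syi: 0.28

reporting:
  precision: 2               # significant figures for display tables

# July concentration estimates, mg m^-3 (mean, se, n) per compartment.
concentrations:
  - {variable: chla, ice_type: ridge, compartment: interior, mean: 2.6, se: 0.9, n: 23}
  - {variable: chla, ice_type: ridge, compartment: exterior, mean: 19.0, se: 9.0, n: 16}
  - {variable: chla, ice_type: ridge, compartment: voids, mean: 3.0, se: 1.0, n: 3}
  - {variable: chla, ice_type: ridge, compartment: bottom, mean: 1.2, se: 0.2, n: 5}
  - {variable: chla, ice_type: fyi, compartment: interior, mean: 0.9, se: 0.1, n: 60}
  - {variable: chla, ice_type: fyi, compartment: bottom, mean: 3.9, se: 0.9, n: 5}
  - {variable: chla, ice_type: syi, compartment: interior, mean: 0.8, se: 0.1, n: 68}
  - {variable: chla, ice_type: syi, compartment: bottom, mean: 3.1, se: 0.7, n: 4}
  - {variable: poc, ice_type: ridge, compartment: interior, mean: 420.0, se: 60.0, n: 21}
  - {variable: poc, ice_type: ridge, compartment: exterior, mean: 410.0, se: 100.0, n: 6}
  - {variable: poc, ice_type: ridge, compartment: voids, mean: 100.0, se: 30.0, n: 3}
  - {variable: poc, ice_type: ridge, compartment: bottom, mean: 390.0, se: 60.0, n: 5}
  - {variable: poc, ice_type: fyi, compartment: interior, mean: 280.0, se: 30.0, n: 54}
  - {variable: poc, ice_type: fyi, compartment: bottom, mean: 950.0, se: 220.0, n: 5}
  - {variable: poc, ice_type: syi, compartment: interior, mean: 760.0, se: 70.0, n: 73}
  - {variable: poc, ice_type: syi, compartment: bottom, mean: 470.0, se: 100.0, n: 4}
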