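# Robot-assisted radical prostatectomy (RARP) care pathway: two robotic
# platform arms (da Vinci vs Hugo RAS), 19 micro-activities in four macro
# groups, and the resource registry used to derive capacity cost rates.
#
# Capacity conventions (per-year capacity period, 80% practical):
#   * personnel: 100,000 theoretical minutes/year (~1,667 h of contracted
#     clinical time); period_cost is the gross annual employer cost.
#   * platforms: 12 h/day theoretical availability over 300 operating
#     days/year = 216,000 min; period_cost is the annual rental +
#     maintenance fee from the hospital tender.
#   * operating room: 12 h/day over 250 working days/year = 180,000 min;
#     period_cost covers room running costs excluding platform and staff.
# Surgical kits are consumables: attributed per patient, never
# time-allocated, so they carry no capacity.
#
# Staffing quantities follow the process-map roster: nurses are present
# throughout; the anesthesia team covers induction and stays through the
# case via the nurse anesthesiologist; prep and positioning staffs 2.5
# nurses (one present half the time), the senior surgeon, the senior
# anesthesiologist and two medical trainees; the console phase staffs two
# senior surgeons and two junior surgeons. This is one defensible reading
# of the published roster legend, not a verbatim trial roster.
# "platform_{arm}" resolves to the patient's arm at costing time.

arms: [davinci, hugo]

resources:
  - {id: nurse, name: Theater nurse, category: personnel,
     period_cost: 38000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: senior_surgeon, name: Senior surgeon, category: personnel,
     period_cost: 105000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: junior_surgeon, name: Junior surgeon, category: personnel,
     period_cost: 55000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: senior_anesthesiologist, name: Senior anesthesiologist, category: personnel,
     period_cost: 95000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: nurse_anesthesiologist, name: Nurse anesthesiologist, category: personnel,
     period_cost: 42000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: medical_trainee, name: Medical trainee, category: personnel,
     period_cost: 22000, theoretical_capacity: 100000, practical_fraction: 0.8}
  - {id: platform_davinci, name: da Vinci platform (rental + maintenance), category: platform,
     period_cost: 335000, theoretical_capacity: 216000, practical_fraction: 0.8}
  - {id: platform_hugo, name: Hugo RAS platform (rental + maintenance), category: platform,
     period_cost: 415000, theoretical_capacity: 216000, practical_fraction: 0.8}
  - {id: operating_room, name: Operating room, category: operating_room,
     period_cost: 273000, theoretical_capacity: 180000, practical_fraction: 0.8}
  - {id: kit_davinci, name: da Vinci surgical kit, category: consumable}
  - {id: kit_hugo, name: Hugo RAS surgical kit, category: consumable}

activities:
  # -- room setup -----------------------------------------------------
  - id: room_configuration
    name: Room configuration
    macro_group: room_setup
    staffing: {nurse: 2, "platform_{arm}": 1, operating_room: 1}
  - id: platform_draping
    name: Draping of platform
    macro_group: room_setup
    staffing: {nurse: 2, "platform_{arm}": 1, operating_room: 1}
  # -- anesthesia -----------------------------------------------------
  - id: anesthesia
    name: Anesthesia (procedure and latency)
    macro_group: anesthesia
    staffing: {nurse: 2, senior_anesthesiologist: 1, nurse_anesthesiologist: 1,
               "platform_{arm}": 1, operating_room: 1}
  # -- prep and positioning -------------------------------------------
  - id: patient_positioning
    name: Patient positioning
    macro_group: prep_positioning
    staffing: &prep_staffing
      {nurse: 2.5, senior_surgeon: 1, senior_anesthesiologist: 1,
       medical_trainee: 2, "platform_{arm}": 1, operating_room: 1}
  - id: patient_draping_cables
    name: Draping of patient and cable connection
    macro_group: prep_positioning
    staffing: *prep_staffing
  - id: docking
    name: Docking
    macro_group: prep_positioning
    staffing: *prep_staffing
  # -- surgery ---------------------------------------------------------
  - id: trocar_placement
    name: Trocar placement
    macro_group: surgery
    staffing: &surgery_staffing
      {senior_surgeon: 2, junior_surgeon: 2, nurse: 2, nurse_anesthesiologist: 1,
       "platform_{arm}": 1, operating_room: 1}
  - id: lnd
    name: Lymph node dissection (LND)
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: fascia_opening
    name: Opening of the umbilical-prevesical fascia
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: retzius_space
    name: Preparation of the Retzius space
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: bladder_neck
    name: Dissection of the bladder neck
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: seminal_vesicles
    name: Dissection of the seminal vesicles
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: posterior_plane
    name: Dissection of the posterior plane
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: pedicle_nerve_sparing
    name: Prostatic pedicles and nerve sparing
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: apex_urethra
    name: Dissection of the prostate apex and urethra
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  - id: reconstruction_anastomosis
    name: Posterior reconstruction and ureterovesical anastomosis
    macro_group: surgery
    console: true
    staffing: *surgery_staffing
  # -- prep and positioning (closing steps) ----------------------------
  - id: specimen_extraction
    name: Extraction of the operative specimen
    macro_group: prep_positioning
    staffing: *prep_staffing
  - id: undocking
    name: Undocking
    macro_group: prep_positioning
    staffing: *prep_staffing
  # -- room setup (closing step) ----------------------------------------
  - id: platform_undraping
    name: Undraping of platform
    macro_group: room_setup
    staffing: {nurse: 2, "platform_{arm}": 1, operating_room: 1}
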