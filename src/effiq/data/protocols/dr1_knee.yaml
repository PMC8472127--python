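# DR system 1 flat panel, knee protocol (PA, manual).
system_id: DR1
protocol: knee
tube_voltage_kV: 57
sid_cm: 110
tube_load_mAs: 8.5
filtration: 0/0
beam_mode: cone
sdd_cm: 50
object_plane_offset_cm: 20
pixel_pitch_mm: 0.143
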