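# DR system 2 flat panel, knee protocol (PA, manual).
system_id: DR2
protocol: knee
tube_voltage_kV: 63
sid_cm: 115
tube_load_mAs: 6.3
filtration: 0/0
beam_mode: cone
sdd_cm: 55
object_plane_offset_cm: 20
pixel_pitch_mm: 0.139
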