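# DR system 1 flat panel, chest protocol (PA, AEC).
system_id: DR1
protocol: chest
tube_voltage_kV: 133
sid_cm: 250
tube_load_mAs: 1.6
filtration: 1/0.2
beam_mode: cone
sdd_cm: 190
object_plane_offset_cm: 28
pixel_pitch_mm: 0.143
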