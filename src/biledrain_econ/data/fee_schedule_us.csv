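label,category,amount,country
EUS-BD,bundled-strategy-initial,8002.48,US
Re-intervention with PTBD after failed EUS-BD,bundled-strategy-reintervention,6351.83,US
PTBD,bundled-strategy-initial,13369.98,US
Re-intervention after failed PTBD,bundled-strategy-reintervention,957.11,US
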