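fluoxetina
paracetamol
diazepam
amitriptilina
omeprazol
dipirona
glicose
captopril
insulina
nimesulida
clorpromazina
enalapril
imipramina
sinvastatina
carbamazepina
amoxicilina
ibuprofeno
metformina
risperidona
atenolol
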