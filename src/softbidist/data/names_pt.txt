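# Synthetic Portuguese personal-name list authored for this package
# (generator input; not drawn from any published benchmark).
joão
maria
josé
antónio
francisco
fernanda
gonçalves
henrique
conceição
sebastião
rodrigues
ferreira
oliveira
carvalho
machado
teixeira
azevedo
cristóvão
madalena
margarida
leonardo
salvador
estêvão
beatriz
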