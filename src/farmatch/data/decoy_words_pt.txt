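paciente
pacientes
tomando
tomar
tomou
comprimido
comprimidos
capsula
capsulas
receita
receitado
prescrito
prescricao
medicamento
medicamentos
remedio
remedios
consulta
consultorio
retorno
exame
exames
resultado
resultados
pressao
arterial
cabeca
dores
febre
tosse
gripe
dieta
jejum
manha
tarde
noite
dormir
sono
insonia
ansiedade
depressao
tristeza
choro
familia
filho
filha
esposa
marido
trabalho
casa
rua
bairro
posto
saude
unidade
agenda
semana
semanas
meses
anos
idade
peso
altura
gotas
xarope
pomada
injecao
vacina
curativo
ferida
alergia
coceira
mancha
pele
garganta
ouvido
nariz
olhos
barriga
estomago
intestino
urina
sangue
colesterol
diabetes
hipertensao
asma
bronquite
refluxo
gastrite
azia
enjoo
vomito
diarreia
constipacao
cansaco
fraqueza
tontura
desmaio
queixa
relata
refere
nega
orientado
orientada
encaminhado
encaminhada
avaliacao
seguimento
acompanhamento
melhora
piora
quadro
estavel
usando
suspenso
aumentada
reduzida
dose
doses
diaria
continuo
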